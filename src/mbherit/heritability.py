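"""SNP heritability of taxon abundances via a Bayesian sparse linear mixed model.

Model: y = 1_n mu + X beta + u + e, with a spike-and-slab prior on the
per-SNP effects beta (inclusion probability pi, log-uniform hyperprior), a
polygenic effect u ~ N(0, sigma_b^2 tau^-1 K) whose covariance is the
centered genomic relationship matrix, and Gaussian residuals e with
precision tau.  Hyperparameters follow the model's standard
parametrization: h in (0,1) is the expected fraction of variance explained
by genetics, rho in (0,1) the fraction of that due to the sparse term, and
both carry uniform priors.

The sampler works in the eigenbasis of K, where the residual-plus-polygenic
covariance is diagonal; mu, beta and tau are integrated analytically out of
the Metropolis–Hastings target (Gaussian prior on the sparse effects, a
diffuse Gaussian on mu, Jeffreys prior on tau), so each iteration updates
only the inclusion set gamma and (h, rho, log pi).  Retained draws sample
tau, mu, beta and u back from their exact conditionals; the per-draw
heritability is PVE = var(X beta + u) / (var(X beta + u) + tau^-1), with
the empirical variance taken over samples.  Chains are deterministic given
the config seed.

A polygenic-only REML estimator over the same eigendecomposition serves as
an independent cross-check of the MCMC on sparse-free simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .io_qc import GenotypeMatrix


@dataclass
class BslmmConfig:
    """Sampler settings; the default chain length is a desk-scale run —
    for production estimates raise `n_mcmc` (1e5 is a typical setting)."""

    n_mcmc: int = 20_000
    burn_in: int | None = None          # default: n_mcmc // 4
    thin: int | None = None             # default: keep ~500 draws
    h_step: float = 0.10
    rho_step: float = 0.15
    logpi_step: float = 0.75
    mu_prior_var: float = 1e6
    max_gamma: int = 300
    seed: int = 0

    def resolved(self) -> tuple[int, int]:
        burn = self.n_mcmc // 4 if self.burn_in is None else self.burn_in
        if not self.n_mcmc > burn >= 0:
            raise ValueError("need n_mcmc > burn_in >= 0")
        thin = self.thin if self.thin is not None else max(1, (self.n_mcmc - burn) // 500)
        return burn, thin


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned draws of the model unknowns."""

    mu: np.ndarray                       # (n_draws,)
    tau: np.ndarray                      # (n_draws,)
    h: np.ndarray
    rho: np.ndarray
    logpi: np.ndarray
    gamma: list[np.ndarray]              # sparse-effect SNP indices per draw
    beta: list[np.ndarray]               # matching effect sizes
    u: np.ndarray                        # (n_draws, n) polygenic draws
    n_samples: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.tau)

    def inclusion_probability(self, p: int) -> np.ndarray:
        out = np.zeros(p)
        for g in self.gamma:
            out[g] += 1
        return out / max(1, self.n_draws)


@dataclass
class HeritabilityEstimate:
    taxon_id: str
    pve_point: float
    ci_low: float
    ci_high: float
    n_draws: int
    heritable: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.pve_point <= self.ci_high:
            raise ValueError("point estimate must lie inside the interval")


def _as_array(obj) -> np.ndarray:
    if isinstance(obj, GenotypeMatrix):
        return np.asarray(obj.dosage, dtype=float)
    return np.asarray(getattr(obj, "values", obj), dtype=float)


def bslmm_fit(y: np.ndarray, G, K, cfg: BslmmConfig | None = None) -> PosteriorDraws:
    """Run the BSLMM MCMC and return retained posterior draws."""
    cfg = cfg or BslmmConfig()
    y = np.asarray(y, dtype=float)
    X = _as_array(G)
    Kv = _as_array(K)
    n, p = X.shape
    if len(y) != n or Kv.shape != (n, n):
        raise ValueError("y, G and K dimensions disagree")
    if np.isnan(X).any():
        raise ValueError("genotypes must be complete; mean-impute first")
    if y.std() == 0:
        raise ValueError("zero-variance trait")
    if n < 30:
        print(f"[heritability] warning: n={n} is small for heritability estimation")
    burn, thin = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)

    d, U = np.linalg.eigh(Kv)
    if d.min() < -1e-8 * max(1.0, np.trace(Kv) / n):
        raise ValueError("kinship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    kbar = d.sum() / n
    if kbar == 0:
        raise ValueError("kinship matrix is zero")

    Xc = X - X.mean(axis=0)
    s_a = max(Xc.var(axis=0).mean(), 1e-12)
    yt = U.T @ y
    Xt = U.T @ Xc
    it = U.T @ np.ones(n)

    logpi_lo, logpi_hi = np.log(1.0 / p), 0.0

    def log_target(gamma: list[int], h: float, rho: float, logpi: float):
        """Collapsed log posterior (up to a constant); returns the pieces
        needed to resample (tau, coefficients) at retained iterations."""
        k = len(gamma)
        pi = np.exp(logpi)
        sigma_b2 = h * (1 - rho) / ((1 - h) * kbar)
        V = sigma_b2 * d + 1.0
        Vi = 1.0 / V
        if k:
            sigma_a2 = h * rho / ((1 - h) * pi * p * s_a)
            W = np.column_stack([it, Xt[:, gamma]])
            Svec = np.concatenate([[cfg.mu_prior_var], np.full(k, sigma_a2)])
        else:
            W = it[:, None]
            Svec = np.array([cfg.mu_prior_var])
        WtVi = W.T * Vi
        M = WtVi @ W
        M[np.diag_indices_from(M)] += 1.0 / Svec
        cf = cho_factor(M, lower=True)
        b = WtVi @ yt
        alpha = cho_solve(cf, b)
        q = float(yt @ (Vi * yt) - b @ alpha)
        if q <= 0:
            return -np.inf, None
        logdet_M = 2.0 * np.log(np.diag(cf[0])).sum()
        ll = (-0.5 * np.log(V).sum() - 0.5 * np.log(Svec).sum()
              - 0.5 * logdet_M - 0.5 * n * np.log(q))
        lp_gamma = k * logpi + (p - k) * np.log1p(-min(pi, 1 - 1e-12))
        return ll + lp_gamma, (cf, alpha, q, sigma_b2, W)

    def reflect(x: float, lo: float, hi: float) -> float:
        span = hi - lo
        x = (x - lo) % (2 * span)
        return lo + (x if x <= span else 2 * span - x)

    # initial state
    h, rho, logpi = 0.5, 0.5, np.log(min(10.0 / p, 1.0))
    logpi = max(logpi, logpi_lo)
    gamma: list[int] = []
    cur, aux = log_target(gamma, h, rho, logpi)

    draws = PosteriorDraws(mu=[], tau=[], h=[], rho=[], logpi=[],
                           gamma=[], beta=[], u=[], n_samples=n)  # type: ignore[arg-type]
    mu_l, tau_l, h_l, rho_l, lp_l, u_l = [], [], [], [], [], []

    for it_no in range(cfg.n_mcmc):
        # --- gamma move: add / remove / swap ---
        k = len(gamma)
        move = rng.random()
        prop = None
        if move < 0.4 and k < min(cfg.max_gamma, p):
            j = int(rng.integers(p))
            if j not in gamma:
                prop = gamma + [j]
                # forward: 0.4/p (membership draws propose the current state);
                # reverse remove: 0.4/(k+1)
                log_q = np.log(p) - np.log(k + 1)
        elif move < 0.8 and k > 0:
            drop = int(rng.integers(k))
            prop = gamma[:drop] + gamma[drop + 1:]
            log_q = np.log(k) - np.log(p)
        elif k > 0:
            drop = int(rng.integers(k))
            j = int(rng.integers(p))
            if j not in gamma:
                prop = gamma[:drop] + gamma[drop + 1:] + [j]
                log_q = 0.0
        if prop is not None:
            new, new_aux = log_target(prop, h, rho, logpi)
            if np.log(rng.random()) < new - cur + log_q:
                gamma, cur, aux = prop, new, new_aux

        # --- joint hyperparameter move (reflected random walk, symmetric) ---
        cand = (reflect(h + cfg.h_step * rng.standard_normal(), 1e-4, 1 - 1e-4),
                reflect(rho + cfg.rho_step * rng.standard_normal(), 1e-4, 1 - 1e-4),
                reflect(logpi + cfg.logpi_step * rng.standard_normal(), logpi_lo, logpi_hi))
        new, new_aux = log_target(gamma, *cand)
        if np.log(rng.random()) < new - cur:
            h, rho, logpi = cand
            cur, aux = new, new_aux

        if it_no >= burn and (it_no - burn) % thin == 0:
            cf, alpha, q, sigma_b2, W = aux
            tau = rng.gamma(n / 2.0, 2.0 / q)
            z = rng.standard_normal(len(alpha))
            # coef ~ N(alpha, tau^-1 M^-1): back-substitute L^T x = z
            coef = alpha + solve_triangular(cf[0], z, lower=True, trans="T") / np.sqrt(tau)
            zt = yt - W @ coef
            c = sigma_b2 * d / (sigma_b2 * d + 1.0)
            ut = c * zt + np.sqrt(c / tau) * rng.standard_normal(n)
            mu_l.append(coef[0]); tau_l.append(tau); h_l.append(h)
            rho_l.append(rho); lp_l.append(logpi)
            draws.gamma.append(np.array(gamma, dtype=int))
            draws.beta.append(np.array(coef[1:], dtype=float))
            u_l.append(U @ ut)

    draws.mu = np.array(mu_l)
    draws.tau = np.array(tau_l)
    draws.h = np.array(h_l)
    draws.rho = np.array(rho_l)
    draws.logpi = np.array(lp_l)
    draws.u = np.array(u_l)
    return draws


def pve_from_draws(d: PosteriorDraws, X, K=None) -> np.ndarray:
    """Per-draw PVE = var(X beta + u) / (var(X beta + u) + tau^-1).

    The empirical variance is taken over samples; X is column-centered
    before applying the sparse effects.  K is accepted for interface
    symmetry (u draws already embed its structure).
    """
    if d.n_draws == 0:
        raise ValueError("no retained draws")
    X = _as_array(X)
    Xc = X - X.mean(axis=0)
    out = np.empty(d.n_draws)
    for i in range(d.n_draws):
        g = d.u[i].copy()
        if len(d.gamma[i]):
            g += Xc[:, d.gamma[i]] @ d.beta[i]
        vg = g.var()
        out[i] = vg / (vg + 1.0 / d.tau[i])
    return out


def pve_interval(pve_draws: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(median, lower, upper) after trimming the extreme (1-level)/2 tails."""
    pve_draws = np.asarray(pve_draws, dtype=float)
    if len(pve_draws) < 40:
        raise ValueError("need at least 40 draws for a tail-trimmed interval")
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(pve_draws, [tail, 100 - tail])
    return float(np.median(pve_draws)), float(lo), float(hi)


def classify_heritable(est: HeritabilityEstimate, threshold: float = 0.15) -> bool:
    """A taxon is called heritable when its point h2 exceeds the threshold (strict)."""
    return est.pve_point > threshold


def estimate_heritability(
    y: np.ndarray, G, K, cfg: BslmmConfig | None = None, taxon_id: str = "",
    threshold: float = 0.15,
) -> HeritabilityEstimate:
    """Convenience wrapper: fit, derive PVE draws, trim tails, classify."""
    draws = bslmm_fit(y, G, K, cfg)
    pve = pve_from_draws(draws, G, K)
    point, lo, hi = pve_interval(pve)
    est = HeritabilityEstimate(taxon_id, point, lo, hi, len(pve))
    est.heritable = classify_heritable(est, threshold)
    return est


def reml_pve_oracle(y: np.ndarray, K) -> float:
    """Polygenic-only REML heritability, used as an MCMC cross-check.

    Fits y = 1 mu + u + e with u ~ N(0, sigma_u^2 K / kbar) (K rescaled to
    unit mean diagonal so sigma_u^2 is the per-sample genetic variance) by
    profiling the restricted likelihood over the variance ratio on the
    eigenbasis of K.  Returns sigma_u^2 / (sigma_u^2 + sigma_e^2).
    """
    y = np.asarray(y, dtype=float)
    Kv = _as_array(K)
    n = len(y)
    d, U = np.linalg.eigh(Kv)
    d = np.clip(d, 0.0, None)
    kbar = d.sum() / n
    if kbar == 0:
        raise ValueError("kinship matrix is zero")
    d = d / kbar
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        V = lam * d + 1.0
        xv = xt / V
        xvx = xt @ xv
        mu_hat = (xv @ yt) / xvx
        r = yt - mu_hat * xt
        rss = r @ (r / V)
        if rss <= 0 or xvx <= 0:
            return np.inf
        sigma_e2 = rss / (n - 1)
        return 0.5 * (np.log(V).sum() + np.log(xvx)
                      + (n - 1) * (np.log(sigma_e2) + 1.0))

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res}")
    lam = float(np.exp(res.x))
    return lam / (1.0 + lam)
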