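"""Hierarchical shoot-root allometry, root mass fraction, and per-accession
drought biomass tests with unequal variances.

Model
-----
For plant j of accession i with shoot weight x and root weight y:

    ln y_ij = a_i + k_i * ln x_ij + e_ij,   e_ij ~ Normal(0, sigma^2)
    a_i ~ Normal(mu_a, tau_a^2),  k_i ~ Normal(mu_k, tau_k^2)

a_i is the log intercept (ln b_i) and k_i the allometric slope. Priors are
weakly informative and configurable: mu_k ~ N(0,1), mu_a ~ N(-1, 2^2),
half-Normal(1) on tau_a, tau_k and sigma. The posterior is sampled by a
Gibbs scheme: (a_i, k_i) and the population means have conjugate normal
conditionals; the three scale parameters are updated with univariate slice
sampling. Convergence is gated on split R-hat <= 1.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seeds import substream
from .tables import BiomassTable


@dataclass(frozen=True)
class AllometryPriors:
    mu_k_mean: float = 0.0
    mu_k_sd: float = 1.0
    mu_a_mean: float = -1.0
    mu_a_sd: float = 2.0
    tau_scale: float = 1.0
    sigma_scale: float = 1.0
    #: lower bound keeping the posterior proper on exactly noiseless data
    sigma_floor: float = 1e-4


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    rhat_threshold: float = 1.05


@dataclass
class AllometryPosterior:
    """Posterior draws and summaries of the hierarchical allometry fit."""

    accessions: list[str]
    draws: dict[str, np.ndarray]  # name -> (chains, draws[, accessions])
    summary: pd.DataFrame  # per-accession posterior means and 95% CrIs
    population: pd.DataFrame  # population-level parameter summary
    rhat: dict[str, float]
    converged: bool
    seed: int

    def k_mean(self) -> pd.Series:
        return self.summary.set_index("genotype")["k_mean"]

    def overall_line(self) -> tuple[float, float]:
        """Population-level (ln b, k): the overall allometric relationship."""
        pop = self.population.set_index("parameter")
        return float(pop.loc["mu_a", "mean"]), float(pop.loc["mu_k", "mean"])


def _split_rhat(x: np.ndarray) -> float:
    """Split R-hat over (chains, draws) sample array."""
    c, n = x.shape
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = halves.shape
    chain_means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n2 * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def _slice_sample(x0: float, logp, rng, width: float = 0.5, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""

    def lp(x):
        v = logp(x)
        return v if np.isfinite(v) or v == -np.inf else -np.inf

    y0 = lp(x0)
    if y0 == -np.inf:  # pathological start; leave the state unchanged
        return x0
    y = y0 - rng.exponential()
    u = rng.uniform()
    left = x0 - width * u
    right = left + width
    steps = max_steps
    while steps > 0 and lp(left) > y:
        left -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and lp(right) > y:
        right += width
        steps -= 1
    for _ in range(1000):
        x1 = rng.uniform(left, right)
        if lp(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def fit_allometry_bhm(
    biomass: BiomassTable,
    priors: AllometryPriors = AllometryPriors(),
    mcmc: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    regime: str | None = None,
) -> AllometryPosterior:
    """Fit the hierarchical log-log allometry model.

    ``regime`` restricts the fit to one watering regime (control and
    drought are modelled separately). Non-convergence (split R-hat above
    the threshold on any monitored parameter) flags the result rather than
    raising.
    """
    df = biomass.data if regime is None else biomass.subset_regime(regime).data
    genos = sorted(df["genotype"].unique())
    G = len(genos)
    lx = [np.log(df.loc[df["genotype"] == g, "shoot_dw_g"].to_numpy()) for g in genos]
    ly = [np.log(df.loc[df["genotype"] == g, "root_dw_g"].to_numpy()) for g in genos]
    for g, v in zip(genos, lx):
        if len(v) < 2:
            raise ValueError(f"accession {g} has fewer than 2 plants")
    # per-accession sufficient statistics
    n_i = np.array([len(v) for v in lx], dtype=float)
    Sx = np.array([v.sum() for v in lx])
    Sxx = np.array([(v**2).sum() for v in lx])
    Sy = np.array([v.sum() for v in ly])
    Syy = np.array([(v**2).sum() for v in ly])
    Sxy = np.array([(a * b).sum() for a, b in zip(lx, ly)])
    N = n_i.sum()

    def rss(a, k):
        return np.sum(
            Syy
            - 2 * a * Sy
            - 2 * k * Sxy
            + 2 * a * k * Sx
            + a**2 * n_i
            + k**2 * Sxx
        )

    chains: dict[str, list[np.ndarray]] = {
        "a": [], "k": [], "mu_a": [], "mu_k": [], "tau_a": [], "tau_k": [], "sigma": []
    }
    n_keep = mcmc.n_draws
    for chain in range(mcmc.n_chains):
        rng = substream(seed, f"bhm_chain{chain}")
        # init at per-accession ridge-stabilised OLS
        denom = np.maximum(n_i * Sxx - Sx**2, 1e-8)
        k = (n_i * Sxy - Sx * Sy) / denom
        k = np.clip(k, -2.0, 2.0)
        a = (Sy - k * Sx) / n_i
        mu_a, mu_k = a.mean(), k.mean()
        tau_a = max(a.std(), 0.1) * rng.uniform(0.5, 2.0)
        tau_k = max(k.std(), 0.1) * rng.uniform(0.5, 2.0)
        sigma = max(
            np.sqrt(max(rss(a, k), 1e-6) / N) * rng.uniform(0.5, 2.0),
            2 * priors.sigma_floor,
        )
        keep = {name: [] for name in chains}
        for it in range(mcmc.n_warmup + n_keep):
            inv_s2 = 1.0 / sigma**2
            # collapsed draw of (mu_a, mu_k) with accession effects integrated
            # out: X'V^-1 X = (s^2 (X'X)^-1 + T)^-1 per accession (full
            # column rank), which is numerically stable for tiny sigma,
            # unlike the direct Woodbury difference
            xdet = n_i * Sxx - Sx**2  # > 0 when shoot weights are distinct
            g11 = Sxx / xdet
            g12 = -Sx / xdet
            g22 = n_i / xdet
            w11 = sigma**2 * g11 + tau_a**2
            w12 = sigma**2 * g12
            w22 = sigma**2 * g22 + tau_k**2
            wdet = w11 * w22 - w12**2
            c11 = w22 / wdet
            c12 = -w12 / wdet
            c22 = w11 / wdet
            # OLS coefficients per accession; d = C @ ols
            ols_a = g11 * Sy + g12 * Sxy
            ols_k = g12 * Sy + g22 * Sxy
            d1 = np.sum(c11 * ols_a + c12 * ols_k)
            d2 = np.sum(c12 * ols_a + c22 * ols_k)
            c11, c12, c22 = np.sum(c11), np.sum(c12), np.sum(c22)
            p11 = c11 + 1.0 / priors.mu_a_sd**2
            p12 = c12
            p22 = c22 + 1.0 / priors.mu_k_sd**2
            r1 = d1 + priors.mu_a_mean / priors.mu_a_sd**2
            r2 = d2 + priors.mu_k_mean / priors.mu_k_sd**2
            det = p11 * p22 - p12**2
            mean_a = (p22 * r1 - p12 * r2) / det
            mean_k = (p11 * r2 - p12 * r1) / det
            l11 = np.sqrt(p11)
            l21 = p12 / l11
            l22 = np.sqrt(np.maximum(p22 - l21**2, 1e-300))
            z2 = rng.standard_normal()
            z1 = rng.standard_normal()
            dmk = z2 / l22
            mu_k = mean_k + dmk
            mu_a = mean_a + (z1 - l21 * dmk) / l11
            # scale parameters: slice sampling against the marginal
            # likelihood given the population means (accession effects
            # integrated out) — updating them against (a_i, k_i) directly
            # mixes too slowly through the location-scale funnel
            rr = (
                Syy
                - 2 * mu_a * Sy
                - 2 * mu_k * Sxy
                + mu_a**2 * n_i
                + 2 * mu_a * mu_k * Sx
                + mu_k**2 * Sxx
            )
            u1 = Sy - mu_a * n_i - mu_k * Sx
            u2 = Sxy - mu_a * Sx - mu_k * Sxx

            def marginal_logp(ta, tk, s):
                if ta <= 0 or tk <= 0 or s < priors.sigma_floor:
                    return -np.inf
                s2 = s * s
                # log det(s^2 I + X T X') via the determinant lemma
                det2 = (1 + ta**2 * n_i / s2) * (1 + tk**2 * Sxx / s2) - (
                    ta**2 * tk**2 * Sx**2 / s2**2
                )
                logdet = 2 * n_i * np.log(s) + np.log(det2)
                # quadratic form via Woodbury: B = (s^2 T^-1 + X'X)^-1
                m11 = s2 / ta**2 + n_i
                m12 = Sx
                m22 = s2 / tk**2 + Sxx
                mdet = m11 * m22 - m12**2
                quad = (
                    rr - (m22 * u1**2 - 2 * m12 * u1 * u2 + m11 * u2**2) / mdet
                ) / s2
                lp = -0.5 * np.sum(logdet + quad)
                lp -= ta**2 / (2 * priors.tau_scale**2)
                lp -= tk**2 / (2 * priors.tau_scale**2)
                lp -= s**2 / (2 * priors.sigma_scale**2)
                return lp

            tau_a = _slice_sample(tau_a, lambda t: marginal_logp(t, tau_k, sigma), rng)
            tau_k = _slice_sample(tau_k, lambda t: marginal_logp(tau_a, t, sigma), rng)
            sigma = _slice_sample(sigma, lambda s: marginal_logp(tau_a, tau_k, s), rng)
            # joint conjugate draw of (a_i, k_i) given the updated
            # hyperparameters (last, so stored draws match them)
            inv_s2 = 1.0 / sigma**2
            p11 = n_i * inv_s2 + 1.0 / tau_a**2
            p12 = Sx * inv_s2
            p22 = Sxx * inv_s2 + 1.0 / tau_k**2
            r1 = Sy * inv_s2 + mu_a / tau_a**2
            r2 = Sxy * inv_s2 + mu_k / tau_k**2
            det = p11 * p22 - p12**2
            mean_a = (p22 * r1 - p12 * r2) / det
            mean_k = (p11 * r2 - p12 * r1) / det
            l11 = np.sqrt(p11)
            l21 = p12 / l11
            l22 = np.sqrt(np.maximum(p22 - l21**2, 1e-300))
            z1 = rng.standard_normal(G)
            z2 = rng.standard_normal(G)
            dk = z2 / l22
            da = (z1 - l21 * dk) / l11
            a = mean_a + da
            k = mean_k + dk
            if it >= mcmc.n_warmup:
                keep["a"].append(a.copy())
                keep["k"].append(k.copy())
                keep["mu_a"].append(mu_a)
                keep["mu_k"].append(mu_k)
                keep["tau_a"].append(tau_a)
                keep["tau_k"].append(tau_k)
                keep["sigma"].append(sigma)
        for name in chains:
            chains[name].append(np.asarray(keep[name]))

    draws = {name: np.stack(arrs) for name, arrs in chains.items()}  # (C, D, ...)
    rhat: dict[str, float] = {}
    for name in ("mu_a", "mu_k", "tau_a", "tau_k", "sigma"):
        rhat[name] = _split_rhat(draws[name])
    for gi, g in enumerate(genos):
        rhat[f"a[{g}]"] = _split_rhat(draws["a"][:, :, gi])
        rhat[f"k[{g}]"] = _split_rhat(draws["k"][:, :, gi])
    converged = all(v <= mcmc.rhat_threshold for v in rhat.values())

    def summarize(x):  # x flat draws
        return float(np.mean(x)), float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975))

    rows = []
    for gi, g in enumerate(genos):
        am, alo, ahi = summarize(draws["a"][:, :, gi].ravel())
        km, klo, khi = summarize(draws["k"][:, :, gi].ravel())
        rows.append(
            dict(genotype=g, lnb_mean=am, lnb_lo=alo, lnb_hi=ahi,
                 k_mean=km, k_lo=klo, k_hi=khi)
        )
    summary = pd.DataFrame(rows)
    pop_rows = []
    for name in ("mu_a", "mu_k", "tau_a", "tau_k", "sigma"):
        m, lo, hi = summarize(draws[name].ravel())
        pop_rows.append(dict(parameter=name, mean=m, lo=lo, hi=hi))
    population = pd.DataFrame(pop_rows)
    return AllometryPosterior(
        accessions=genos,
        draws=draws,
        summary=summary,
        population=population,
        rhat=rhat,
        converged=converged,
        seed=seed,
    )


def ols_slopes(biomass: BiomassTable, regime: str | None = None) -> pd.Series:
    """Independent per-accession OLS slopes of ln(root) on ln(shoot)."""
    df = biomass.data if regime is None else biomass.subset_regime(regime).data
    out = {}
    for g, sub in df.groupby("genotype"):
        lx = np.log(sub["shoot_dw_g"].to_numpy())
        ly = np.log(sub["root_dw_g"].to_numpy())
        res = stats.linregress(lx, ly)
        out[g] = res.slope
    return pd.Series(out).sort_index()


def compute_rmf(biomass: BiomassTable) -> pd.DataFrame:
    """Per-plant RMF = root / (root + shoot), averaged per accession x regime."""
    df = biomass.data.copy()
    df["rmf"] = df["root_dw_g"] / (df["root_dw_g"] + df["shoot_dw_g"])
    agg = (
        df.groupby(["genotype", "regime"], as_index=False)["rmf"]
        .mean()
        .rename(columns={"rmf": "rmf_mean"})
    )
    return agg


@dataclass
class DroughtBiomassTest:
    """Per-accession drought-vs-control comparisons with per-group variances."""

    results: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: genotype, trait, mean_control, mean_drought, estimate, se,
    #          df, p_value, pct_change, flagged


def test_drought_biomass(biomass: BiomassTable) -> DroughtBiomassTest:
    """Welch-type two-group tests per accession for shoot, root and total."""
    df = biomass.data.copy()
    df["total_dw_g"] = df["shoot_dw_g"] + df["root_dw_g"]
    traits = {"shoot": "shoot_dw_g", "root": "root_dw_g", "total": "total_dw_g"}
    rows = []
    for g, sub in df.groupby("genotype"):
        ctrl = sub[sub["regime"] == "control"]
        drt = sub[sub["regime"] == "drought"]
        for trait, col in traits.items():
            x = ctrl[col].to_numpy()
            y = drt[col].to_numpy()
            flagged = len(x) < 2 or len(y) < 2
            mc, md = float(np.mean(x)) if len(x) else np.nan, float(np.mean(y)) if len(y) else np.nan
            est = md - mc
            if flagged:
                rows.append(dict(genotype=g, trait=trait, mean_control=mc,
                                 mean_drought=md, estimate=est, se=np.nan,
                                 df=np.nan, p_value=np.nan,
                                 pct_change=100 * est / mc if mc else np.nan,
                                 flagged=True))
                continue
            v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
            n1, n2 = len(x), len(y)
            se2 = v1 / n1 + v2 / n2
            if se2 == 0:
                p = 1.0 if est == 0 else 0.0
                se = 0.0
                dof = n1 + n2 - 2
            else:
                se = float(np.sqrt(se2))
                dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
                t = est / se
                p = float(2 * stats.t.sf(abs(t), dof))
            rows.append(dict(genotype=g, trait=trait, mean_control=mc,
                             mean_drought=md, estimate=est, se=se, df=float(dof),
                             p_value=p, pct_change=100 * est / mc, flagged=False))
    return DroughtBiomassTest(pd.DataFrame(rows))
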