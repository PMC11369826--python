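"""Bayesian hierarchical linear mixed models for ROI/channel epoch values.

Three model kinds mirror the analysis questions:

* ``group``:    value ~ 1 + group (sum-contrast: PD = +1, HC = -1)
                + (1 | participant)
* ``condition``: value ~ 1 + condition (sum contrasts over
                freeze/stop/successful) + (1 + condition | participant)
* ``severity``: value ~ 1 + pct_time_frozen + updrs (centred/standardised)
                + (1 | participant), PD participants only

Likelihood: y = X beta + Z u + eps with independent Gaussian random
effects per term and Gaussian residuals.  Priors are flat (improper) on
the fixed effects and half-normal(scale) on every standard-deviation
component (flat priors alone are not samplable for variances; the
half-normal(1) default is weakly informative on the z-scored response
scale).  Posterior draws come from a blocked Gibbs sampler with slice
steps for the standard deviations; the posterior contract is checked by
recovery and calibration tests, not tied to a particular sampler.

Sum-contrast convention: the group coefficient is the deviation of PD
from the grand mean, so the PD-HC difference equals twice the
coefficient; summaries report both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd


@dataclass
class ModelSpec:
    kind: str = "group"            # group | condition | severity
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    seed: int = 0
    prior_sd_scale: float = 1.0    # half-normal scale for all sd components
    rhat_threshold: float = 1.01
    keep_ranef: bool = False

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.kind not in ("group", "condition", "severity"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class PosteriorFit:
    """Posterior summary plus raw draws (chains x draws per effect)."""

    summary: pd.DataFrame
    draws: dict
    ranef: dict = field(default_factory=dict)  # term -> Series of posterior means
    converged: bool = True

    def effect(self, name: str) -> pd.Series:
        return self.summary.set_index("effect").loc[name]


# ------------------------------------------------------------- Gibbs core


@dataclass
class _RandomTerm:
    name: str
    groups: np.ndarray   # int codes per row
    x: np.ndarray        # per-row multiplier
    n_groups: int
    sd_name: str


def _slice_sample_log_sd(logp, x0: float, rng: np.random.Generator,
                         w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampler (stepping out + shrinkage) on log-sd."""
    y = logp(x0) - rng.exponential(1.0)
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1 - u)
    for _ in range(max_steps):
        if logp(lo) < y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < y:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logp(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _gibbs_chain(y, X, terms, sd_names, n_iter, rng, prior_scale, keep_from):
    """Blocked Gibbs: all location parameters (beta, u) drawn jointly from
    their Gaussian conditional; sds by slice sampling."""
    n, p = X.shape
    # full design: fixed-effect columns then one column per (term, group)
    blocks = [X]
    offsets = {}
    m = p
    for t in terms:
        Z = np.zeros((n, t.n_groups))
        Z[np.arange(n), t.groups] = t.x
        blocks.append(Z)
        offsets[t.name] = (m, m + t.n_groups)
        m += t.n_groups
    F = np.hstack(blocks)
    FtF = F.T @ F
    Fty = F.T @ y

    sigma = max(float(np.std(y)), 0.1) * float(np.exp(0.2 * rng.standard_normal()))
    sds = {nm: 0.5 * prior_scale * float(np.exp(0.3 * rng.standard_normal()))
           for nm in sd_names}
    theta = np.zeros(m)

    out_beta = np.empty((n_iter - keep_from, p))
    out_sd = np.empty((n_iter - keep_from, 1 + len(sd_names)))
    out_u = {t.name: np.empty((n_iter - keep_from, t.n_groups)) for t in terms}

    prior_prec = np.zeros(m)
    for it in range(n_iter):
        # joint draw of (beta, u) | sds
        for t in terms:
            a, b = offsets[t.name]
            prior_prec[a:b] = 1.0 / sds[t.sd_name] ** 2
        A = FtF / sigma ** 2 + np.diag(prior_prec)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Fty / sigma ** 2)
        z = rng.standard_normal(m)
        theta = mean + np.linalg.solve(L.T, z)
        beta = theta[:p]
        u = {t.name: theta[slice(*offsets[t.name])] for t in terms}
        resid = y - F @ theta
        # residual sd
        ssr = float(resid @ resid)

        def logp_sigma(ls):
            s = np.exp(ls)
            return (-n * ls - ssr / (2 * s ** 2) - s ** 2 / (2 * prior_scale ** 2) + ls)

        sigma = float(np.exp(_slice_sample_log_sd(logp_sigma, np.log(sigma), rng)))
        # random-effect sds (possibly shared across terms)
        for nm in sd_names:
            us = np.concatenate([u[t.name] for t in terms if t.sd_name == nm])
            q = len(us)
            ss = float(us @ us)

            def logp_sd(ls, q=q, ss=ss):
                s = np.exp(ls)
                return (-q * ls - ss / (2 * s ** 2) - s ** 2 / (2 * prior_scale ** 2) + ls)

            sds[nm] = float(np.exp(_slice_sample_log_sd(logp_sd, np.log(sds[nm]), rng)))

        if it >= keep_from:
            j = it - keep_from
            out_beta[j] = beta
            out_sd[j, 0] = sigma
            for k_sd, nm in enumerate(sd_names):
                out_sd[j, 1 + k_sd] = sds[nm]
            for t in terms:
                out_u[t.name][j] = u[t.name]
    return out_beta, out_sd, out_u


def _fit_lmm(y, X, fixed_names, terms, spec: ModelSpec):
    sd_names = list(dict.fromkeys(t.sd_name for t in terms))
    rngs = [np.random.default_rng(np.random.SeedSequence([spec.seed % (2**31), 101, c]))
            for c in range(spec.chains)]
    n_iter = spec.warmup + spec.draws
    betas, sds_all, us_all = [], [], []
    for rng in rngs:
        b, s, u = _gibbs_chain(y, X, terms, sd_names, n_iter, rng,
                               spec.prior_sd_scale, spec.warmup)
        betas.append(b)
        sds_all.append(s)
        us_all.append(u)
    draws = {nm: np.stack([b[:, j] for b in betas])
             for j, nm in enumerate(fixed_names)}
    draws["sigma"] = np.stack([s[:, 0] for s in sds_all])
    for m, nm in enumerate(sd_names):
        draws[f"sd_{nm}"] = np.stack([s[:, 1 + m] for s in sds_all])
    ranef_draws = {t.name: np.stack([u[t.name] for u in us_all]) for t in terms}
    return draws, ranef_draws


def summarize_draws(draws: dict, rhat_threshold: float = 1.01) -> tuple[pd.DataFrame, bool]:
    """Posterior means, 95%/99% CrIs, exclusion flags and convergence
    diagnostics for a dict of (chains x draws) arrays."""
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rows = []
    converged = True
    for name, d in draws.items():
        flat = d.reshape(-1)
        lo95, hi95 = np.quantile(flat, [0.025, 0.975])
        lo99, hi99 = np.quantile(flat, [0.005, 0.995])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(np.asarray(az.rhat(idata, var_names=[name]).to_array()).ravel()[0])
            ess = float(np.asarray(az.ess(idata, var_names=[name]).to_array()).ravel()[0])
        if np.isfinite(rhat) and rhat > rhat_threshold:
            converged = False
        rows.append(dict(effect=name, mean=float(flat.mean()), sd=float(flat.std()),
                         q2_5=float(lo95), q97_5=float(hi95),
                         q0_5=float(lo99), q99_5=float(hi99),
                         excludes_zero_95=bool(lo95 > 0 or hi95 < 0),
                         excludes_zero_99=bool(lo99 > 0 or hi99 < 0),
                         rhat=rhat, ess=ess))
    return pd.DataFrame(rows), converged


# ------------------------------------------------------------- model builders


def _participant_codes(table: pd.DataFrame):
    cats = pd.Categorical(table["participant"])
    if len(cats.categories) < 2:
        raise ValueError("at least 2 participants are required")
    return np.asarray(cats.codes, dtype=int), list(cats.categories)


CONDITION_CLASSES = ("freeze", "stop", "successful")


def condition_class(cond: pd.Series) -> pd.Series:
    return cond.where(cond.isin(["freeze", "stop"]), "successful")


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> PosteriorFit:
    """Fit one hierarchical model to an epoch-table subset (typically one
    ROI and window)."""
    y = table["value"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    codes, participants = _participant_codes(table)
    nq = len(participants)
    ones = np.ones(len(y))
    terms = [_RandomTerm("u0", codes, ones, nq, "participant")]

    if spec.kind == "group":
        g = np.where(table["group"].to_numpy() == "PD", 1.0, -1.0)
        X = np.column_stack([ones, g])
        fixed = ["intercept", "group"]
    elif spec.kind == "condition":
        cls = condition_class(table["condition"]).to_numpy()
        c1 = np.where(cls == "freeze", 1.0, np.where(cls == "successful", -1.0, 0.0))
        c2 = np.where(cls == "stop", 1.0, np.where(cls == "successful", -1.0, 0.0))
        X = np.column_stack([ones, c1, c2])
        fixed = ["intercept", "cond_c1", "cond_c2"]
        terms.append(_RandomTerm("u_c1", codes, c1, nq, "cond_slope"))
        terms.append(_RandomTerm("u_c2", codes, c2, nq, "cond_slope"))
    else:  # severity
        cols = []
        fixed = ["intercept"]
        for cov in ("pct_time_frozen", "updrs"):
            v = table[cov].to_numpy(dtype=float)
            if np.nanstd(v) <= 1e-12:
                raise ValueError(f"degenerate covariate {cov!r} (no variation)")
            cols.append((v - np.nanmean(v)) / np.nanstd(v))
            fixed.append(cov)
        X = np.column_stack([ones] + cols)

    draws, ranef_draws = _fit_lmm(y, X, fixed, terms, spec)
    if spec.kind == "group":
        draws["group_PD_minus_HC"] = 2.0 * draws["group"]
    summary, converged = summarize_draws(draws, spec.rhat_threshold)
    if not converged:
        warnings.warn("R-hat above threshold; inspect the posterior summary")
    ranef = {}
    if spec.keep_ranef:
        for name, d in ranef_draws.items():
            ranef[name] = pd.Series(d.reshape(-1, d.shape[-1]).mean(axis=0),
                                    index=participants)
    return PosteriorFit(summary=summary, draws=draws, ranef=ranef, converged=converged)


def condition_contrasts(fit: PosteriorFit,
                        pairs: tuple = (("freeze", "stop"),
                                        ("freeze", "successful"),
                                        ("stop", "successful"))) -> pd.DataFrame:
    """Pairwise condition contrasts computed on the posterior draws (not
    refit).  Level means under sum coding: freeze = b0 + c1, stop =
    b0 + c2, successful = b0 - c1 - c2."""
    b1, b2 = fit.draws["cond_c1"], fit.draws["cond_c2"]
    level = {"freeze": b1, "stop": b2, "successful": -b1 - b2}
    out = {}
    for a, b in pairs:
        out[f"{a}_minus_{b}"] = level[a] - level[b]
    summary, _ = summarize_draws(out)
    return summary


def channel_maps(channel_table: pd.DataFrame, spec: ModelSpec,
                 effect: str = "intercept") -> pd.DataFrame:
    """One model per channel; star level from CrI exclusion of zero
    (none / 95 / 99) for the requested effect."""
    rows = []
    for i, (ch, sub) in enumerate(channel_table.groupby("roi_or_channel", sort=True)):
        sp = ModelSpec(**{**spec.__dict__, "seed": spec.seed + 13 * i})
        fit = fit_model(sub, sp)
        eff = fit.effect(effect)
        star = "99" if eff["excludes_zero_99"] else ("95" if eff["excludes_zero_95"] else "none")
        rows.append(dict(channel=ch, mean=eff["mean"], q2_5=eff["q2_5"],
                         q97_5=eff["q97_5"], q0_5=eff["q0_5"], q99_5=eff["q99_5"],
                         star=star, rhat=eff["rhat"]))
    return pd.DataFrame(rows)


def severity_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> PosteriorFit:
    """Severity model: %-time-frozen and motor-score fixed effects
    (standardised internally) with a participant random intercept."""
    spec = spec or ModelSpec(kind="severity")
    if spec.kind != "severity":
        spec = ModelSpec(**{**spec.__dict__, "kind": "severity"})
    return fit_model(table, spec)


# ------------------------------------------------------------- simulators


def simulate_group_table(n_participants: int = 20, events_per: int = 30,
                         beta_intercept: float = 0.0, beta_group: float = 0.2,
                         sigma_u: float = 0.3, sigma: float = 1.0,
                         seed: int = 0, roi: str = "PFC") -> pd.DataFrame:
    """Simulate an ROI epoch table from the group model's own generative
    process (used for recovery and calibration checks)."""
    rng = np.random.default_rng(int(seed) % (2**31))
    rows = []
    for i in range(n_participants):
        group = "PD" if i % 2 == 0 else "HC"
        g = 1.0 if group == "PD" else -1.0
        u = rng.normal(0, sigma_u)
        vals = beta_intercept + beta_group * g + u + rng.normal(0, sigma, events_per)
        for j, v in enumerate(vals):
            rows.append(dict(participant=f"sub-{i + 1:02d}", group=group,
                             subgroup="none", run="run-01", event_id=f"e{j}",
                             condition="stop", direction="none", roi_or_channel=roi,
                             window="early", value=float(v),
                             pct_time_frozen=np.nan, updrs=np.nan))
    return pd.DataFrame(rows)


def simulate_condition_table(n_participants: int = 20, events_per: int = 20,
                             means: dict | None = None, sigma_u: float = 0.3,
                             sigma_slope: float = 0.2, sigma: float = 1.0,
                             seed: int = 0) -> pd.DataFrame:
    """Simulate a freeze/stop/successful epoch table with participant
    random intercepts and condition slopes."""
    means = means or {"freeze": 0.0, "stop": 0.0, "successful": 0.0}
    rng = np.random.default_rng(int(seed) % (2**31))
    rows = []
    for i in range(n_participants):
        u = rng.normal(0, sigma_u)
        dev = rng.normal(0, sigma_slope, 3)
        for k, cond in enumerate(CONDITION_CLASSES):
            vals = means[cond] + u + dev[k] + rng.normal(0, sigma, events_per)
            for j, v in enumerate(vals):
                rows.append(dict(participant=f"sub-{i + 1:02d}", group="PD",
                                 subgroup="none", run="run-01",
                                 event_id=f"{cond}{j}", condition=cond,
                                 direction="none", roi_or_channel="PFC",
                                 window="early", value=float(v),
                                 pct_time_frozen=np.nan, updrs=np.nan))
    return pd.DataFrame(rows)


def simulate_severity_table(n_participants: int = 20, events_per: int = 20,
                            slope_pct: float = 0.3, slope_updrs: float = 0.0,
                            sigma_u: float = 0.3, sigma: float = 1.0,
                            seed: int = 0) -> pd.DataFrame:
    """Simulate PD participants whose ROI response scales with standardised
    %-time-frozen (and optionally motor score)."""
    rng = np.random.default_rng(int(seed) % (2**31))
    pct = rng.normal(13.0, 8.0, n_participants)
    updrs = rng.normal(44.0, 10.0, n_participants)
    pct_z = (pct - pct.mean()) / pct.std()
    upd_z = (updrs - updrs.mean()) / updrs.std()
    rows = []
    for i in range(n_participants):
        u = rng.normal(0, sigma_u)
        mu = slope_pct * pct_z[i] + slope_updrs * upd_z[i] + u
        vals = mu + rng.normal(0, sigma, events_per)
        for j, v in enumerate(vals):
            rows.append(dict(participant=f"sub-{i + 1:02d}", group="PD",
                             subgroup="none", run="run-01", event_id=f"e{j}",
                             condition="doorway", direction="none",
                             roi_or_channel="PFC", window="early", value=float(v),
                             pct_time_frozen=float(pct[i]), updrs=float(updrs[i])))
    return pd.DataFrame(rows)
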