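"""Bayesian models for the quantification assays.

Three normal-likelihood models on log-scale responses, sampled with an
affine-invariant ensemble MCMC (emcee):

- Western densitometry: log(band density / total-protein density) with a
  strain x condition mean, a lineage random intercept, and a residual; the
  headline statistic is P_diff, the posterior probability that a strain
  differs from wild type in the observed direction within the same medium
  and phase.
- ChIP-qPCR enrichment: per-replicate dCq = Cq(IP) - Cq(input), target minus
  the mean of two control amplicons, giving a log2 enrichment whose
  evidence against zero is a Savage-Dickey log10 Bayes factor with the
  conventional tiers 0.5-1 (*), 1-2 (**), >2 (***).
- ddCq expression effects: dCq against a set of reference transcripts, then
  the mutant-vs-WT difference, signed so positive means higher expression in
  the mutant.

Priors are weakly informative (means centred on the data mean with scale
2.5x the data SD, half-normal scales) and are recorded on every summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "fit_western_model",
    "fit_chip_qpcr_model",
    "fit_ddcq_model",
    "bayes_factor",
    "significance_tier",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings. Walkers are the ensemble's parallel chains;
    convergence is flagged when the split-Rhat over walkers exceeds 1.01."""

    n_walkers: int = 48
    n_steps: int = 3000
    n_burn: int = 1000
    seed: int = 0
    rhat_tol: float = 1.01


@dataclass
class PosteriorSummary:
    """Posterior mean with 95% credible bounds plus, where applicable, the
    posterior probability of a directional difference (P_diff in [0.5, 1])
    and a Savage-Dickey log10 Bayes factor against a zero effect."""

    value: float
    ci_lo: float
    ci_hi: float
    p_diff: float | None = None
    direction: str | None = None
    log10_bf: float | None = None
    n_draws: int = 0
    seed: int = 0
    converged: bool = True
    prior: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, abs(self.value))  # degenerate posteriors round
        if not (self.ci_lo - tol <= self.value <= self.ci_hi + tol):
            raise ValueError("credible interval must bracket the posterior mean")
        if self.p_diff is not None and not (0.5 - 1e-9 <= self.p_diff <= 1 + 1e-9):
            raise ValueError("P_diff must lie in [0.5, 1]")


def _split_rhat(chain: np.ndarray, n_groups: int = 4) -> float:
    """Max split-Rhat over dimensions for a (steps, walkers, ndim) chain.

    Individual ensemble walkers are strongly autocorrelated, so they are
    pooled into ``n_groups`` pseudo-chains (each additionally split in half
    along time) before the standard Rhat variance comparison; this flags a
    non-stationary or badly initialised ensemble without demanding that
    every walker individually decorrelates.
    """
    n, w, ndim = chain.shape
    half = n // 2
    g = max(1, w // n_groups)
    pieces = []
    for start in range(0, g * n_groups, g):
        block = chain[:, start : start + g, :]          # (steps, g, ndim)
        pieces.append(block[:half].reshape(-1, ndim))
        pieces.append(block[half : 2 * half].reshape(-1, ndim))
    x = np.stack(pieces, axis=1)                        # (samples, chains, ndim)
    worst = 0.0
    m = x.shape[0]
    for d in range(ndim):
        xd = x[:, :, d]
        within = xd.var(axis=0, ddof=1).mean()
        between = m * xd.mean(axis=0).var(ddof=1)
        if within <= 0:
            continue
        var_hat = (m - 1) / m * within + between / m
        worst = max(worst, float(np.sqrt(var_hat / within)))
    return worst


def _sample(log_prob, p0_center, p0_scale, cfg: MCMCConfig):
    """Run the ensemble sampler; returns (flat draws, converged flag)."""
    center = np.asarray(p0_center, dtype=float)
    ndim = center.size
    nw = max(cfg.n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(cfg.seed)
    p0 = center + p0_scale * rng.standard_normal((nw, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(cfg.seed).get_state())
    sampler.run_mcmc(state, cfg.n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=cfg.n_burn)
    converged = _split_rhat(chain) <= cfg.rhat_tol
    return chain.reshape(-1, ndim), converged


def _ci(draws: np.ndarray) -> tuple[float, float, float]:
    return (
        float(draws.mean()),
        float(np.percentile(draws, 2.5)),
        float(np.percentile(draws, 97.5)),
    )


def _p_diff(delta_draws: np.ndarray) -> tuple[float, str]:
    p_hi = float(np.mean(delta_draws > 0))
    if p_hi >= 0.5:
        return p_hi, "higher"
    return 1.0 - p_hi, "lower"


def bayes_factor(
    effect_draws: np.ndarray,
    prior_sd: float,
    prior_mean: float = 0.0,
    point: float = 0.0,
) -> float:
    """Savage-Dickey log10 Bayes factor for a nonzero effect.

    BF10 = prior density at the point null / posterior density at the point
    null, the posterior density being a Gaussian KDE over the draws. A
    posterior with no mass near the null is floored so the BF stays finite.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    prior_at_0 = stats.norm.pdf(point, loc=prior_mean, scale=prior_sd)
    draws = np.asarray(effect_draws, dtype=float)
    if np.ptp(draws) == 0:
        post_at_0 = np.inf if draws[0] == point else 0.0
    else:
        post_at_0 = float(stats.gaussian_kde(draws)(point)[0])
    post_at_0 = max(post_at_0, 1e-12)
    return float(np.log10(prior_at_0 / post_at_0))


def significance_tier(log10_bf: float) -> str:
    """Conventional evidence tiers on the log10 Bayes factor."""
    if log10_bf > 2:
        return "***"
    if log10_bf > 1:
        return "**"
    if log10_bf > 0.5:
        return "*"
    return "n.s."


# ---------------------------------------------------------------------------
# Western-blot model

def fit_western_model(
    table: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    reference_strain: str = "WT",
) -> dict[tuple[str, str, str], PosteriorSummary]:
    """Hierarchical model for relative protein levels from blot densitometry.

    ``table`` needs columns strain, medium, phase, lineage, biorep,
    lrp_density, total_density. The response is log(lrp/total); the model is

        y ~ Normal(theta[strain, medium, phase] + u[lineage], sigma)
        u ~ Normal(0, tau)

    with the lineage random intercept ``u`` integrated out analytically
    (each lineage block then has covariance sigma^2 I + tau^2 J, inverted by
    Sherman-Morrison), which removes the location ridge and the tau funnel
    that slow ensemble samplers on the centred parameterisation.

    Returns one summary per strain x condition: the posterior mean log level
    with its 95% CI, and for non-reference strains P_diff — the posterior
    probability of a difference vs the reference strain in the same medium
    and phase, in the direction the posterior favours.

    The knockout (scar) strain has no protein band and must be excluded from
    the table; non-positive densities are rejected.
    """
    cfg = mcmc or MCMCConfig()
    required = {"strain", "medium", "phase", "lineage", "biorep", "lrp_density", "total_density"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    if (table["strain"] == "scar").any():
        raise ValueError("the scar strain carries no band and must be excluded")
    if (table["lrp_density"] <= 0).any() or (table["total_density"] <= 0).any():
        raise ValueError("densities must be positive")

    df = table.sort_values(["strain", "medium", "phase", "lineage", "biorep"]).reset_index(drop=True)
    y = np.log(df["lrp_density"].to_numpy() / df["total_density"].to_numpy())
    cells = sorted(set(zip(df["strain"], df["medium"], df["phase"])))
    cell_idx = np.array([cells.index(c) for c in zip(df["strain"], df["medium"], df["phase"])])
    lineages = sorted(df["lineage"].unique())
    lin_idx = np.array([lineages.index(l) for l in df["lineage"]])

    nc, nl = len(cells), len(lineages)
    ybar, ysd = float(y.mean()), float(max(y.std(), 1e-3))
    prior = {
        "theta": ("normal", ybar, 2.5 * ysd),
        "u": ("normal", 0.0, "tau", "marginalized"),
        "tau": ("halfnormal", ysd),
        "sigma": ("halfnormal", 2.5 * ysd),
    }
    # lineage indicator for block sums; k = observations per lineage
    lin_onehot = np.zeros((y.size, nl))
    lin_onehot[np.arange(y.size), lin_idx] = 1.0
    k = lin_onehot.sum(axis=0)

    def log_prob(params: np.ndarray) -> np.ndarray:
        theta = params[:, :nc]
        log_tau = params[:, nc]
        log_sigma = params[:, nc + 1]
        bad = (np.abs(log_tau) > 12) | (np.abs(log_sigma) > 12)
        tau2 = np.exp(2 * log_tau)
        sig2 = np.exp(2 * log_sigma)
        r = y[None, :] - theta[:, cell_idx]
        q = np.sum(r * r, axis=1)
        s = r @ lin_onehot                      # per-lineage residual sums
        denom = sig2[:, None] + k[None, :] * tau2[:, None]
        ll = (
            -0.5 * q / sig2
            + 0.5 * (tau2[:, None] / (sig2[:, None] * denom) * s * s).sum(axis=1)
            - 0.5 * ((k[None, :] - 1) * 2 * log_sigma[:, None] + np.log(denom)).sum(axis=1)
        )
        lp = (
            -0.5 * np.sum(((theta - ybar) / (2.5 * ysd)) ** 2, axis=1)
            - 0.5 * np.exp(2 * log_tau) / ysd**2 + log_tau      # half-normal + Jacobian
            - 0.5 * sig2 / (2.5 * ysd) ** 2 + log_sigma
        )
        out = ll + lp
        out[bad] = -np.inf
        return out

    cell_means = np.array([y[cell_idx == i].mean() for i in range(nc)])
    rsd = max(float((y - cell_means[cell_idx]).std()), 1e-6)
    p0 = np.concatenate([cell_means, [np.log(rsd), np.log(rsd)]])
    draws, converged = _sample(log_prob, p0, rsd, cfg)
    theta_draws = draws[:, :nc]

    out: dict[tuple[str, str, str], PosteriorSummary] = {}
    for i, cell in enumerate(cells):
        strain, medium, phase = cell
        value, lo, hi = _ci(theta_draws[:, i])
        p_diff = direction = None
        ref = (reference_strain, medium, phase)
        if strain != reference_strain and ref in cells:
            delta = theta_draws[:, i] - theta_draws[:, cells.index(ref)]
            p_diff, direction = _p_diff(delta)
        out[cell] = PosteriorSummary(
            value, lo, hi, p_diff, direction,
            n_draws=theta_draws.shape[0], seed=cfg.seed, converged=converged,
            prior=prior,
        )
    return out


# ---------------------------------------------------------------------------
# ChIP-qPCR enrichment model

def _delta_cq(sub: pd.DataFrame) -> pd.DataFrame:
    """Per strain x amplicon x replicate dCq = Cq(IP) - Cq(input)."""
    wide = sub.pivot_table(
        index=["strain", "amplicon", "rep"], columns="fraction", values="cq"
    )
    if not {"IP", "input"} <= set(wide.columns):
        raise ValueError("cq table must contain both 'IP' and 'input' fractions")
    wide = wide.dropna(subset=["IP", "input"])
    wide["dcq"] = wide["IP"] - wide["input"]
    return wide.reset_index()


def fit_chip_qpcr_model(
    cq_table: pd.DataFrame,
    controls: Sequence[str],
    mcmc: MCMCConfig | None = None,
    reference_strain: str = "WT",
    prior_scale: float = 4.0,
) -> dict[tuple[str, str], PosteriorSummary]:
    """Log2 ChIP enrichment at target amplicons relative to control regions.

    ``cq_table`` is tidy with columns strain, amplicon, fraction (IP/input),
    rep, cq. Per replicate the enrichment at a target is

        e = mean(dCq over the two controls) - dCq(target)   [log2 units]

    modelled as e ~ Normal(mu[strain, target], sigma) with mu ~
    Normal(0, prior_scale) — the prior that also anchors the Savage-Dickey
    Bayes factor reported per summary. Missing control amplicons are
    rejected.
    """
    cfg = mcmc or MCMCConfig()
    controls = list(controls)
    if len(controls) != 2:
        raise ValueError("exactly two control amplicons are required")
    present = set(cq_table["amplicon"])
    if not set(controls) <= present:
        raise ValueError(f"control amplicons missing from table: {set(controls) - present}")

    dcq = _delta_cq(cq_table.sort_values(["strain", "amplicon", "rep", "fraction"]))
    ctrl = (
        dcq[dcq["amplicon"].isin(controls)]
        .groupby(["strain", "rep"])["dcq"]
        .mean()
        .rename("ctrl_dcq")
    )
    targets = sorted(a for a in present if a not in controls)
    tgt = dcq[dcq["amplicon"].isin(targets)].join(ctrl, on=["strain", "rep"])
    tgt = tgt.dropna(subset=["ctrl_dcq"])
    tgt["enrichment"] = tgt["ctrl_dcq"] - tgt["dcq"]

    strains = sorted(tgt["strain"].unique())
    cells = [(s, t) for s in strains for t in targets]
    cell_idx = np.array([cells.index((s, t)) for s, t in zip(tgt["strain"], tgt["amplicon"])])
    e = tgt["enrichment"].to_numpy(dtype=float)
    nc = len(cells)
    esd = float(max(np.std(e), 1e-3))
    prior = {"mu": ("normal", 0.0, prior_scale), "sigma": ("halfnormal", 2.5 * esd)}

    def log_prob(params: np.ndarray) -> np.ndarray:
        mu = params[:, :nc]
        log_sigma = params[:, nc]
        bad = np.abs(log_sigma) > 12
        sigma = np.exp(log_sigma)
        resid = e[None, :] - mu[:, cell_idx]
        ll = -0.5 * np.sum((resid / sigma[:, None]) ** 2, axis=1) - e.size * log_sigma
        lp = (
            -0.5 * np.sum((mu / prior_scale) ** 2, axis=1)
            - 0.5 * (sigma / (2.5 * esd)) ** 2 + log_sigma
        )
        out = ll + lp
        out[bad] = -np.inf
        return out

    cell_means = np.array([
        e[cell_idx == i].mean() if np.any(cell_idx == i) else 0.0 for i in range(nc)
    ])
    rsd = max(float((e - cell_means[cell_idx]).std()), 1e-6)
    p0 = np.concatenate([cell_means, [np.log(rsd)]])
    draws, converged = _sample(log_prob, p0, rsd, cfg)

    out: dict[tuple[str, str], PosteriorSummary] = {}
    for i, (strain, target) in enumerate(cells):
        if not np.any(cell_idx == i):
            continue
        mu_draws = draws[:, i]
        value, lo, hi = _ci(mu_draws)
        bf = bayes_factor(mu_draws, prior_sd=prior_scale)
        p_diff = direction = None
        ref = (reference_strain, target)
        if strain != reference_strain and ref in cells and np.any(cell_idx == cells.index(ref)):
            delta = mu_draws - draws[:, cells.index(ref)]
            p_diff, direction = _p_diff(delta)
        out[(strain, target)] = PosteriorSummary(
            value, lo, hi, p_diff, direction, log10_bf=bf,
            n_draws=mu_draws.size, seed=cfg.seed, converged=converged, prior=prior,
        )
    return out


# ---------------------------------------------------------------------------
# ddCq expression model

def fit_ddcq_model(
    qrt_table: pd.DataFrame,
    reference_transcripts: Sequence[str],
    mcmc: MCMCConfig | None = None,
    reference_strain: str = "WT",
) -> dict[tuple[str, str], PosteriorSummary]:
    """ddCq expression effects per gene per genotype, relative to wild type.

    ``qrt_table`` is tidy with columns gene, strain, rep, cq. Per strain and
    replicate, dCq(gene) = Cq(gene) - mean Cq over the reference
    transcripts; each gene is modelled as dCq ~ Normal(m[strain], sigma)
    jointly over strains, and the reported effect for a mutant is

        ddCq effect = m[WT] - m[mutant]   [log2 units]

    so positive values mean higher expression in the mutant. Each summary
    carries P_diff and a Savage-Dickey log10 Bayes factor on the effect.
    """
    cfg = mcmc or MCMCConfig()
    refs = list(reference_transcripts)
    present = set(qrt_table["gene"])
    if not set(refs) <= present:
        raise ValueError(f"reference transcripts missing: {set(refs) - present}")
    df = qrt_table.sort_values(["gene", "strain", "rep"]).reset_index(drop=True)
    ref_cq = (
        df[df["gene"].isin(refs)]
        .groupby(["strain", "rep"])["cq"]
        .mean()
        .rename("ref_cq")
    )
    genes = sorted(g for g in present if g not in refs)
    out: dict[tuple[str, str], PosteriorSummary] = {}

    for gi, gene in enumerate(genes):
        sub = df[df["gene"] == gene].join(ref_cq, on=["strain", "rep"]).dropna(subset=["ref_cq"])
        sub = sub.assign(dcq=sub["cq"] - sub["ref_cq"])
        strains = sorted(sub["strain"].unique())
        if reference_strain not in strains:
            raise ValueError(f"reference strain {reference_strain!r} absent for gene {gene!r}")
        s_idx = np.array([strains.index(s) for s in sub["strain"]])
        yv = sub["dcq"].to_numpy(dtype=float)
        ns = len(strains)
        ybar, ysd = float(yv.mean()), float(max(yv.std(), 1e-3))
        m_scale = 2.5 * ysd
        prior = {
            "m": ("normal", ybar, m_scale),
            "sigma": ("halfnormal", 2.5 * ysd),
            "effect": ("normal", 0.0, float(np.sqrt(2) * m_scale)),
        }

        def log_prob(params: np.ndarray, s_idx=s_idx, yv=yv, ns=ns, ybar=ybar, m_scale=m_scale, ysd=ysd) -> np.ndarray:
            m = params[:, :ns]
            log_sigma = params[:, ns]
            bad = np.abs(log_sigma) > 12
            sigma = np.exp(log_sigma)
            resid = yv[None, :] - m[:, s_idx]
            ll = -0.5 * np.sum((resid / sigma[:, None]) ** 2, axis=1) - yv.size * log_sigma
            lp = (
                -0.5 * np.sum(((m - ybar) / m_scale) ** 2, axis=1)
                - 0.5 * (sigma / (2.5 * ysd)) ** 2 + log_sigma
            )
            res = ll + lp
            res[bad] = -np.inf
            return res

        strain_means = np.array([yv[s_idx == i].mean() for i in range(ns)])
        rsd = max(float((yv - strain_means[s_idx]).std()), 1e-6)
        p0 = np.concatenate([strain_means, [np.log(rsd)]])
        gene_cfg = MCMCConfig(
            cfg.n_walkers, cfg.n_steps, cfg.n_burn, cfg.seed + gi, cfg.rhat_tol
        )
        draws, converged = _sample(log_prob, p0, rsd, gene_cfg)
        m_ref = draws[:, strains.index(reference_strain)]
        for si, strain in enumerate(strains):
            if strain == reference_strain:
                continue
            effect = m_ref - draws[:, si]
            value, lo, hi = _ci(effect)
            p_diff, direction = _p_diff(effect)
            bf = bayes_factor(effect, prior_sd=float(np.sqrt(2) * m_scale))
            out[(gene, strain)] = PosteriorSummary(
                value, lo, hi, p_diff, direction, log10_bf=bf,
                n_draws=effect.size, seed=gene_cfg.seed, converged=converged,
                prior=prior,
            )
    return out


def summaries_to_frame(summaries: Mapping, key_names: Sequence[str]) -> pd.DataFrame:
    """Render a dict of PosteriorSummary into a tidy table with the
    conventional column names value / ci.lo / ci.hi / P_diff / log10_bf."""
    rows = []
    for key, s in summaries.items():
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(key_names, key))
            | {
                "value": s.value,
                "ci.lo": s.ci_lo,
                "ci.hi": s.ci_hi,
                "P_diff": s.p_diff,
                "direction": s.direction,
                "log10_bf": s.log10_bf,
                "n_draws": s.n_draws,
                "seed": s.seed,
                "converged": s.converged,
            }
        )
    return pd.DataFrame(rows)
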