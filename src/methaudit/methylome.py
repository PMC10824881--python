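"""Array-style differential methylation on the M-value scale.

Covers the supervised arm of the audit: the logit2 beta/M transform, the
per-probe SD variance pre-filter, a two-group linear model with
empirical-Bayes variance moderation (closed-form moment matching of the
log residual variances via digamma/trigamma inversion), Benjamini-Hochberg
adjustment, the four-criterion on/off-target probe classifier, and the
collapse of candidate probes to unique genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chromosome: str
    position: int  # 0-based
    gene: str = ""
    cpg_island: bool = False


@dataclass
class ClassifierThresholds:
    """Candidate-probe criteria: BH-adjusted p below ``alpha``; CpG-island
    membership; M-value increase above mean(SD) + ``delta_sd_multiplier`` x
    SD(SD) of the per-probe SD distribution; control mean M below
    ``control_m_max``; treated mean M above ``treated_m_min``. All strict."""

    alpha: float = 0.05
    delta_sd_multiplier: float = 2.0
    variance_sd_multiplier: float = 2.5
    control_m_max: float = -1.0
    treated_m_min: float = -1.0
    sd_rule: str = "offset"  # "offset": mean+k*SD of SDs; "scaled": k*mean(SD)

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sd_rule not in ("offset", "scaled"):
            raise ValueError("sd_rule must be 'offset' or 'scaled'")


@dataclass
class VarianceFilterResult:
    per_probe_sd: pd.Series
    threshold: float
    kept_probe_ids: list[str]


def beta_to_m(beta, epsilon: float = 1e-3):
    """M = log2(b / (1-b)) with b clipped into [epsilon, 1-epsilon]."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-m))
    return float(b) if b.ndim == 0 else b


def per_probe_sd(m_matrix: pd.DataFrame) -> pd.Series:
    """Sample SD of each probe's M-values across all samples (both groups)."""
    if m_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute per-probe SDs")
    return m_matrix.std(axis=1, ddof=1)


def sd_threshold(sds: pd.Series, multiplier: float, rule: str = "offset") -> float:
    if rule == "offset":
        return float(sds.mean() + multiplier * sds.std(ddof=1))
    return float(multiplier * sds.mean())


def variance_filter(m_matrix: pd.DataFrame, multiplier: float = 2.5,
                    rule: str = "offset") -> VarianceFilterResult:
    """Keep probes whose M-value SD lies strictly above the population rule.

    Default rule: mean(per-probe SD) + multiplier x SD(per-probe SD); the
    alternative reading multiplier x mean(SD) is available via ``rule``.
    """
    sds = per_probe_sd(m_matrix)
    thr = sd_threshold(sds, multiplier, rule)
    kept = sds.index[sds > thr].tolist()
    return VarianceFilterResult(per_probe_sd=sds, threshold=thr, kept_probe_ids=kept)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated test

def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float, d0_cap: float = 1e6):
    """Moment-match the scaled-F model for residual variances.

    Works on z = log(s^2): E[z] = log(s0^2) + digamma(d/2) - log(d/2)
    (+ the prior terms), Var[z] = trigamma(d/2) + trigamma(d0/2). When the
    observed variance of z does not exceed trigamma(d/2) there is no finite
    solution and d0 = inf (full shrinkage to s0^2).

    Returns (d0, s0sq, posterior s2~ per probe).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, 1.0))
    # zero residual variances carry no information about the prior
    e = z[ok] - special.digamma(df / 2.0) + np.log(df / 2.0)
    if e.size < 2:
        raise ValueError("need at least 2 probes with positive residual variance")
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    c = evar - float(special.polygamma(1, df / 2.0))
    if c > 0:
        d0 = 2.0 * trigamma_inverse(c)
        if d0 > d0_cap:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        s0sq = float(np.exp(emean))
        post = np.full_like(s2, s0sq)
    return d0, s0sq, post


def moderated_dm_test(m_matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                      include_batch: bool = False,
                      d0_override: float | None = None) -> pd.DataFrame:
    """Two-group differential methylation with moderated t-statistics.

    Fits, per probe, an ordinary linear model with intercept and treated
    indicator (optionally an additive batch term), shrinks the residual
    variances toward a pooled prior via :func:`squeeze_variances`, and
    refers effect / (s~ * sqrt(v)) to a t distribution on d + d0 degrees of
    freedom (standard normal in the full-shrinkage limit d0 = inf).
    ``d0_override=0`` reproduces the classical unmoderated t-test.

    Returns a DataFrame indexed by probe with columns effect, t, df_total,
    p, p_adj, direction; hyperparameters in ``.attrs``.
    """
    samples = m_matrix.columns
    groups = sample_sheet.loc[samples, "group"]
    if set(groups.unique()) - {"control", "treated"}:
        raise ValueError("groups must be 'control' and 'treated'")
    if (groups == "control").sum() < 2 or (groups == "treated").sum() < 2:
        raise ValueError("need at least 2 samples per group")

    x = (groups == "treated").to_numpy(dtype=float)
    cols = [np.ones_like(x), x]
    if include_batch:
        batches = sample_sheet.loc[samples, "batch"]
        for b in sorted(batches.unique())[1:]:
            cols.append((batches == b).to_numpy(dtype=float))
    X = np.column_stack(cols)
    n, p = X.shape
    d = n - np.linalg.matrix_rank(X)
    if d < 1:
        raise ValueError("zero residual degrees of freedom; need >=2 per group")

    Y = m_matrix.to_numpy(dtype=float)  # probes x samples
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = Y @ X @ XtX_inv.T  # probes x p
    resid = Y - B @ X.T
    s2 = (resid ** 2).sum(axis=1) / d
    v = XtX_inv[1, 1]  # variance factor of the group contrast
    effect = B[:, 1]

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            post = s2.copy()
            s0sq = float("nan")
        elif np.isinf(d0):
            _, s0sq, _ = squeeze_variances(s2, d)
            post = np.full_like(s2, s0sq)
        else:
            _, s0sq, _ = squeeze_variances(s2, d)
            post = (d0 * s0sq + d * s2) / (d0 + d)
    else:
        d0, s0sq, post = squeeze_variances(s2, d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(post * v)
    t = np.where((effect == 0), 0.0, t)
    df_total = d + d0
    if np.isfinite(df_total):
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    out = pd.DataFrame({
        "effect": effect,
        "t": t,
        "df_total": df_total,
        "p": pvals,
        "p_adj": bh_adjust(pvals),
        "direction": np.where(effect > 0, "hyper", "hypo"),
        "residual_sd": np.sqrt(s2),
    }, index=m_matrix.index)
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    out.attrs["residual_df"] = d
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# classifier and gene collapse

def classify_probes(dm: pd.DataFrame, m_matrix: pd.DataFrame,
                    sample_sheet: pd.DataFrame,
                    annotations: dict[str, ProbeAnnotation] | list[ProbeAnnotation],
                    thresholds: ClassifierThresholds | None = None,
                    sd_stats: pd.Series | None = None) -> pd.DataFrame:
    """Apply the on/off-target candidate criteria to every tested probe.

    A probe is a candidate iff all of: adjusted p strictly below alpha;
    annotated inside a CpG island; M-value increase strictly above the
    population SD rule (same per-probe SD statistic as the variance filter,
    computed over ``sd_stats`` when the filter ran on a larger matrix);
    control group mean M strictly below ``control_m_max``; treated group
    mean M strictly above ``treated_m_min``. Every criterion is reported as
    its own boolean column for audit output.
    """
    thresholds = thresholds or ClassifierThresholds()
    if isinstance(annotations, list):
        annotations = {a.probe_id: a for a in annotations}
    missing = [pid for pid in m_matrix.index if pid not in annotations]
    if missing:
        raise KeyError(f"annotation missing for probes: {missing[:5]}"
                       f"{'...' if len(missing) > 5 else ''}")
    if not dm.index.equals(m_matrix.index):
        dm = dm.loc[m_matrix.index]

    samples = m_matrix.columns
    groups = sample_sheet.loc[samples, "group"]
    ctrl_mean = m_matrix.loc[:, groups == "control"].mean(axis=1)
    trt_mean = m_matrix.loc[:, groups == "treated"].mean(axis=1)

    sds = sd_stats if sd_stats is not None else per_probe_sd(m_matrix)
    delta_thr = sd_threshold(sds, thresholds.delta_sd_multiplier, thresholds.sd_rule)

    island = pd.Series({pid: annotations[pid].cpg_island for pid in m_matrix.index})
    flags = pd.DataFrame({
        "crit_p_adj": dm["p_adj"] < thresholds.alpha,
        "crit_island": island,
        "crit_delta_m": dm["effect"] > delta_thr,
        "crit_control_m": ctrl_mean < thresholds.control_m_max,
        "crit_treated_m": trt_mean > thresholds.treated_m_min,
    }, index=m_matrix.index)
    flags["candidate"] = flags.all(axis=1)
    flags["effect"] = dm["effect"]
    flags["p_adj"] = dm["p_adj"]
    flags["direction"] = dm["direction"]
    flags["control_mean_m"] = ctrl_mean
    flags["treated_mean_m"] = trt_mean
    flags.attrs["delta_m_threshold"] = delta_thr
    return flags


def collapse_to_genes(classified: pd.DataFrame,
                      annotations: dict[str, ProbeAnnotation] | list[ProbeAnnotation]
                      ) -> pd.DataFrame:
    """Collapse candidate probes to unique genes with supporting evidence.

    Probes without a gene label are conserved under the pseudo-gene
    "intergenic". A gene supported by probes in both directions is marked
    direction "mixed".
    """
    if isinstance(annotations, list):
        annotations = {a.probe_id: a for a in annotations}
    cand = classified[classified["candidate"]]
    rows: dict[str, dict] = {}
    for pid, row in cand.iterrows():
        gene = annotations[pid].gene or "intergenic"
        rec = rows.setdefault(gene, {"probes": [], "directions": [], "p_adjs": []})
        rec["probes"].append(pid)
        rec["directions"].append(row["direction"])
        rec["p_adjs"].append(row["p_adj"])
    out = []
    for gene, rec in rows.items():
        dirs = set(rec["directions"])
        out.append({
            "gene": gene,
            "n_probes": len(rec["probes"]),
            "probes": ",".join(rec["probes"]),
            "direction": rec["directions"][0] if len(dirs) == 1 else "mixed",
            "min_p_adj": float(np.min(rec["p_adjs"])),
        })
    df = pd.DataFrame(out, columns=["gene", "n_probes", "probes", "direction",
                                    "min_p_adj"])
    return df.sort_values(["min_p_adj", "gene"]).set_index("gene") if len(df) \
        else df.set_index("gene")
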