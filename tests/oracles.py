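"""Independent brute-force reimplementations used as test oracles.

Each function re-derives a pipeline rule by the most literal possible
computation (position-by-position scans, double loops, per-gene truth
tables) and stays deliberately ignorant of the package internals.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def naive_guide_scan(genome: str, spacer: str, max_mismatch: int,
                     chrom: str = "chr") -> set:
    """Position-by-position Hamming scan on both strands, NGG PAM.

    Returns {(chrom, start, end, strand, mismatches)}.
    """
    L, k = len(genome), len(spacer)
    hits = set()
    for i in range(L - k - 2):
        pam = genome[i + k : i + k + 3]
        if pam[1:] == "GG" and pam[0] in "ACGT":
            mm = sum(1 for a, b in zip(genome[i : i + k], spacer) if a != b)
            if mm <= max_mismatch:
                hits.add((chrom, i, i + k, "+", mm))
    rc = revcomp(genome)
    for i in range(L - k - 2):
        pam = rc[i + k : i + k + 3]
        if pam[1:] == "GG" and pam[0] in "ACGT":
            mm = sum(1 for a, b in zip(rc[i : i + k], spacer) if a != b)
            if mm <= max_mismatch:
                # map back to forward coordinates
                start = L - (i + k)
                hits.add((chrom, start, start + k, "-", mm))
    return hits


def brute_bh(p: np.ndarray) -> np.ndarray:
    """BH step-up by the literal double-loop definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank0, idx in enumerate(order):
        i = rank0 + 1
        best = min(
            min(m * p[order[j]] / (j + 1) for j in range(rank0, m)), 1.0)
        adj[idx] = best
    return adj


def brute_variance_filter(m: np.ndarray, multiplier: float) -> np.ndarray:
    """Boolean kept mask by direct recomputation of the SD-offset rule."""
    sds = np.array([np.std(row, ddof=1) for row in m])
    thr = sds.mean() + multiplier * np.std(sds, ddof=1)
    return sds > thr


def brute_classify(p_adj, island, delta_m, ctrl_mean, trt_mean, sds,
                   alpha=0.05, delta_mult=2.0, ctrl_max=-1.0, trt_min=-1.0):
    """Literal five-rule candidate mask (all inequalities strict)."""
    thr = np.mean(sds) + delta_mult * np.std(sds, ddof=1)
    out = []
    for i in range(len(p_adj)):
        out.append(p_adj[i] < alpha and bool(island[i]) and delta_m[i] > thr
                   and ctrl_mean[i] < ctrl_max and trt_mean[i] > trt_min)
    return np.array(out)


def brute_proximity(hits, probes, window):
    """All-pairs distance filter; returns {(guide_id, probe_id, distance)}."""
    kept = set()
    for h in hits:
        for pr in probes:
            if pr.chromosome != h.chromosome:
                continue
            if h.start <= pr.position < h.end:
                d = 0
            else:
                d = min(abs(pr.position - h.start), abs(pr.position - (h.end - 1)))
            if d <= window:
                kept.add((h.guide_id, pr.probe_id, d))
    return kept


def brute_label(dm_sig, de_sig, congruent, proximal):
    """Truth-table evaluation of the per-gene label."""
    if dm_sig and de_sig and congruent and proximal:
        return "on_target"
    if dm_sig and de_sig and congruent:
        return "off_target_candidate"
    if dm_sig and de_sig:
        return "incongruent"
    if dm_sig:
        return "methylation_only"
    if de_sig:
        return "expression_only"
    return "unaffected"


def brute_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios with an explicit loop."""
    ref_rows = [g for g in range(counts.shape[0]) if all(c > 0 for c in counts[g])]
    gm = [np.prod([float(c) for c in counts[g]]) ** (1.0 / counts.shape[1])
          for g in ref_rows]
    factors = []
    for j in range(counts.shape[1]):
        ratios = [counts[g, j] / gm[i] for i, g in enumerate(ref_rows)]
        factors.append(np.median(ratios))
    return np.array(factors)
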