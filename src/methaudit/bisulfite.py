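"""Clonal bisulfite sequencing analysis.

In-silico bisulfite conversion, per-clone CpG methylation calling against a
coordinate-matched amplicon reference (clean Sanger-style clone reads, no
gapped alignment), lollipop/composite summaries, region restriction, and
guide-relative methylation asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METHYLATED = 1
UNMETHYLATED = 0
AMBIGUOUS = -1


@dataclass(frozen=True)
class RegionAnnotation:
    """Inclusive range of 1-based CpG site numbers, e.g. the MSP footprint."""

    name: str
    cpg_start: int
    cpg_end: int

    def __post_init__(self):
        if self.cpg_start > self.cpg_end:
            raise ValueError("cpg_start must be <= cpg_end")

    def sites(self) -> list[int]:
        return list(range(self.cpg_start, self.cpg_end + 1))


@dataclass
class RegionReference:
    """Amplicon reference sequence with its indexed CpG offsets."""

    name: str
    sequence: str
    cpg_offsets: dict[int, int]  # 1-based CpG site number -> 0-based offset of the C
    genome_start: int = 0


@dataclass
class CloneMethylationProfile:
    clone_id: str
    region_name: str
    sites: list[int]
    calls: list[int]  # METHYLATED / UNMETHYLATED / AMBIGUOUS per site
    conversion_qc: float  # fraction of non-CpG reference Cs read as T


@dataclass
class CompositeSummary:
    region_name: str
    sites: list[int]
    per_site_frequency: list[float]  # NaN where no informative calls
    per_site_informative: list[int]
    n_clones: int


@dataclass
class AsymmetryReport:
    guide_id: str
    distances: list[int]  # signed bases, negative = upstream
    upstream_fraction: float  # NaN when no qualifying site
    radius_estimate: float  # NaN when no qualifying site
    n_sites: int
    defined: bool = True


def _cpg_positions(sequence: str) -> list[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def bisulfite_convert(sequence: str, methylation_states, conversion_rate: float = 1.0,
                      seed: int | None = None, rng=None, cpg_offsets=None) -> str:
    """Apply in-silico sodium bisulfite conversion to one strand.

    Every cytosine outside a CpG context deaminates to T with probability
    ``conversion_rate``; a CpG cytosine is protected (stays C) when its
    methylation state is True, otherwise converts with the same probability.
    ``conversion_rate=1`` is fully deterministic.
    """
    if not (0.0 < conversion_rate <= 1.0):
        raise ValueError("conversion_rate must be in (0, 1]")
    if cpg_offsets is None:
        cpg_offsets = _cpg_positions(sequence)
    if len(methylation_states) != len(cpg_offsets):
        raise ValueError(
            f"state vector length {len(methylation_states)} does not match "
            f"{len(cpg_offsets)} CpG sites")
    if rng is None:
        rng = np.random.default_rng(seed)
    protected = {off for off, m in zip(cpg_offsets, methylation_states) if m}
    out = list(sequence)
    for i, b in enumerate(out):
        if b == "C" and i not in protected:
            if conversion_rate >= 1.0 or rng.random() < conversion_rate:
                out[i] = "T"
    return "".join(out)


def call_cpg_methylation(clone_read: str, reference: RegionReference,
                         clone_id: str = "clone") -> CloneMethylationProfile:
    """Call methylation per indexed CpG site of one clone read.

    C at the site means the cytosine survived conversion (methylated), T
    means it deaminated (unmethylated); anything else is ambiguous and is
    excluded from downstream denominators. Conversion QC is the fraction of
    non-CpG reference cytosines read as T — on fully converted material it
    should be 1.
    """
    if len(clone_read) != len(reference.sequence):
        raise ValueError(
            f"clone read length {len(clone_read)} != reference length "
            f"{len(reference.sequence)} (indels are not supported)")
    sites = sorted(reference.cpg_offsets)
    calls = []
    for n in sites:
        b = clone_read[reference.cpg_offsets[n]].upper()
        calls.append(METHYLATED if b == "C" else UNMETHYLATED if b == "T" else AMBIGUOUS)
    cpg_cs = set(reference.cpg_offsets.values())
    non_cpg_c = [i for i, b in enumerate(reference.sequence) if b == "C" and i not in cpg_cs]
    qc = (float(np.mean([clone_read[i].upper() == "T" for i in non_cpg_c]))
          if non_cpg_c else float("nan"))
    return CloneMethylationProfile(clone_id=clone_id, region_name=reference.name,
                                   sites=sites, calls=calls, conversion_qc=qc)


def composite_frequencies(profiles: list[CloneMethylationProfile]) -> CompositeSummary:
    """Per-site methylated fraction across clones (the 'composite' row).

    Ambiguous calls drop out of the denominator; a site with zero
    informative calls is reported as missing (NaN), not as 0.
    """
    if not profiles:
        raise ValueError("no clone profiles given")
    sites = profiles[0].sites
    for p in profiles:
        if p.sites != sites:
            raise ValueError("clone profiles cover different site sets")
    calls = np.array([p.calls for p in profiles])
    meth = (calls == METHYLATED).sum(axis=0)
    informative = (calls != AMBIGUOUS).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(informative > 0, meth / np.maximum(informative, 1), np.nan)
    return CompositeSummary(region_name=profiles[0].region_name, sites=list(sites),
                            per_site_frequency=freq.tolist(),
                            per_site_informative=informative.tolist(),
                            n_clones=len(profiles))


def summarize_regions(summary: CompositeSummary, regions: list[RegionAnnotation],
                      methylated_floor: float = 0.5) -> pd.DataFrame:
    """Region-restricted composite statistics (inclusive CpG-number bounds)."""
    freq = dict(zip(summary.sites, summary.per_site_frequency))
    rows = []
    for region in regions:
        vals = np.array([freq[s] for s in region.sites() if s in freq])
        vals = vals[~np.isnan(vals)] if vals.size else vals
        rows.append({
            "region": region.name,
            "cpg_start": region.cpg_start,
            "cpg_end": region.cpg_end,
            "n_sites": int(vals.size),
            "mean_frequency": float(np.mean(vals)) if vals.size else float("nan"),
            "n_methylated_sites": int(np.sum(vals >= methylated_floor)) if vals.size else 0,
        })
    return pd.DataFrame(rows).set_index("region")


def methylation_asymmetry(summary: CompositeSummary, guide_id: str,
                          guide_locus: tuple[int, int, str],
                          cpg_positions: dict[int, int],
                          frequency_floor: float = 0.5) -> AsymmetryReport:
    """Guide-relative asymmetry of methylated sites in a composite.

    Sites at or above ``frequency_floor`` count as methylated. Distances are
    signed base distances from the nearest protospacer edge (negative on the
    guide's 5'-upstream side); sites inside the protospacer contribute
    distance 0 and are excluded from the upstream fraction. The radius
    estimate is the largest absolute distance among qualifying sites.
    """
    from .simulate import signed_guide_distance

    s, e, strand = guide_locus
    distances = []
    for site, f in zip(summary.sites, summary.per_site_frequency):
        if np.isnan(f) or f < frequency_floor:
            continue
        if site not in cpg_positions:
            raise KeyError(f"CpG site {site} missing from position index")
        distances.append(int(signed_guide_distance(cpg_positions[site], s, e, strand)))
    nonzero = [d for d in distances if d != 0]
    if not distances:
        return AsymmetryReport(guide_id=guide_id, distances=[],
                               upstream_fraction=float("nan"),
                               radius_estimate=float("nan"), n_sites=0, defined=False)
    upstream = (float(np.mean([d < 0 for d in nonzero]))
                if nonzero else float("nan"))
    return AsymmetryReport(
        guide_id=guide_id, distances=distances,
        upstream_fraction=upstream,
        radius_estimate=float(max(abs(d) for d in distances)),
        n_sites=len(distances), defined=bool(nonzero))


def lollipop_text(profiles: list[CloneMethylationProfile],
                  summary: CompositeSummary | None = None) -> str:
    """Plain-text lollipop rendering: ● methylated, ○ unmethylated, · ambiguous."""
    glyph = {METHYLATED: "●", UNMETHYLATED: "○", AMBIGUOUS: "·"}
    width = max(len(p.clone_id) for p in profiles) + 2
    lines = [" " * width + " ".join(f"{s:>3d}" for s in profiles[0].sites)]
    for p in profiles:
        lines.append(p.clone_id.ljust(width) + " ".join(f"{glyph[c]:>3}" for c in p.calls))
    if summary is not None:
        lines.append("composite".ljust(width) + " ".join(
            " . " if np.isnan(f) else f"{f:.1f}" for f in summary.per_site_frequency))
    return "\n".join(lines)
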