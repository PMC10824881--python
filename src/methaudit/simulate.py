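"""Synthetic data generator for the targeted-methylation specificity audit.

Emulates every input the audit consumes: a toy genome carrying a CpG island
with an explicit 1-based CpG site index, planted sgRNA protospacers (NGG PAM)
plus near-match decoy sites, a probe manifest with CpG-island membership,
a two-group beta-value matrix with a handful of hyper-methylated target
probes, a gene-level RNA count matrix with the target gene knocked down, and
bisulfite-converted clone reads over amplicon regions of the island.

All randomness flows from a single master seed through labelled substreams,
so adding one output (e.g. more clones) never perturbs another (e.g. the
beta matrix).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .bisulfite import RegionAnnotation, RegionReference, bisulfite_convert
from .guidescan import GuideRNA
from .methylome import ProbeAnnotation, beta_to_m, m_to_beta

_BASES = np.array(list("ACGT"))

#: canonical region table for the default 96-site island (CpG numbers,
#: inclusive on both ends): assay regions flanked by sites 22/57 and 72/96,
#: the two differentially methylated regions, the clinical MSP footprint
#: inside DMR2, the core/minimal promoter and the enhancer.
DEFAULT_REGIONS_96 = (
    ("region1", 22, 57),
    ("region2", 72, 96),
    ("DMR1", 25, 50),
    ("DMR2", 73, 90),
    ("MSP", 76, 87),
    ("core_promoter", 50, 62),
    ("enhancer", 82, 87),
)

# anchor CpG site numbers (as fraction of the index) near which the four
# default guides bind: sg1-3 sit in the second assay region, sg4 in the first
_GUIDE_ANCHOR_FRACTIONS_4 = (0.81, 0.885, 0.77, 0.31)
_GUIDE_STRANDS_4 = ("+", "+", "-", "+")


@dataclass
class SimulationConfig:
    """Study conditions for the simulated audit.

    Defaults emulate the real design: a 762-bp CpG island with 96 indexed
    CpG sites, four guides, methylation deposited within a 20-bp radius with
    a strong 5'-upstream bias, three hyper-methylated target probes with a
    planted M-value shift of +3 over a control level near M = -3, and a
    single target gene knocked down by 2 log2 units.
    """

    seed: int = 0
    genome_length: int = 20_000
    island_span: tuple[int, int] = (9_000, 9_762)
    n_cpg_sites: int = 96
    n_guides: int = 4
    deposition_radius: int = 20
    upstream_bias: float = 0.9
    n_probes: int = 2_000
    n_target_probes: int = 3
    delta_m_target: float = 3.0
    n_samples_per_group: int = 3
    beta_noise_sd: float = 0.5
    n_genes: int = 500
    target_gene_log2fc: float = -2.0
    nb_dispersion: float = 0.1
    n_clones_per_region: int = 50
    bisulfite_conversion_rate: float = 1.0
    # secondary knobs
    n_decoys_per_guide: int = 2
    decoy_mismatches: int = 1
    baseline_meth_prob: float = 0.11
    baseline_jitter: float = 0.02
    max_meth_prob: float = 0.9
    n_island_extra_probes: int = 12
    background_island_fraction: float = 0.3
    n_incongruent_genes: int = 1
    incongruent_log2fc: float = 2.0  # sized like the knockdown, for power
    n_rna_samples_per_group: int = 5
    count_base_mean: float = 200.0
    count_base_sigma: float = 1.0
    target_gene_base_mean: float = 500.0
    target_gene: str = "MGMT"

    def __post_init__(self) -> None:
        s, e = self.island_span
        if not (0 <= s < e <= self.genome_length):
            raise ValueError("island_span must lie within the genome")
        if self.n_target_probes > self.n_probes:
            raise ValueError("n_target_probes cannot exceed n_probes")
        if not (0.0 < self.bisulfite_conversion_rate <= 1.0):
            raise ValueError("bisulfite_conversion_rate must be in (0, 1]")
        if not (0.0 <= self.upstream_bias <= 1.0):
            raise ValueError("upstream_bias must be in [0, 1]")
        if e - s < 2 * self.n_cpg_sites:
            raise ValueError(
                "island too small to host n_cpg_sites non-overlapping CpGs"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["island_span"] = list(self.island_span)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "island_span" in d:
            d["island_span"] = tuple(d["island_span"])
        return cls(**d)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator derived from a master seed and a text label."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass
class MethylationProfile:
    condition: str  # "control" | "treated"
    site_probabilities: dict[int, float]  # 1-based CpG site number -> p


@dataclass
class ReferenceBundle:
    genome: str
    chromosome: str
    island: tuple[int, int]
    cpg_index: dict[int, int]  # 1-based site number -> 0-based genome position of the C
    guides: list[GuideRNA]
    guide_loci: dict[str, tuple[int, int, str]]  # guide_id -> (start, end, strand)
    probes: list[ProbeAnnotation]
    regions: list[RegionAnnotation]
    gene_universe: list[str] = field(default_factory=list)

    def region_reference(self, region: RegionAnnotation) -> RegionReference:
        """Amplicon sequence and within-amplicon CpG offsets for one region."""
        if region.cpg_start not in self.cpg_index or region.cpg_end not in self.cpg_index:
            raise ValueError(f"region {region.name} outside the island CpG index")
        start = self.cpg_index[region.cpg_start]
        end = self.cpg_index[region.cpg_end] + 2
        seq = self.genome[start:end]
        offsets = {
            n: p - start
            for n, p in self.cpg_index.items()
            if region.cpg_start <= n <= region.cpg_end
        }
        return RegionReference(name=region.name, sequence=seq, cpg_offsets=offsets,
                               genome_start=start)


def default_regions(n_cpg_sites: int) -> list[RegionAnnotation]:
    """Canonical region table, rescaled if the index size is not 96."""
    out = []
    for name, a, b in DEFAULT_REGIONS_96:
        if n_cpg_sites != 96:
            a = max(1, round(a * n_cpg_sites / 96))
            b = min(n_cpg_sites, round(b * n_cpg_sites / 96))
        out.append(RegionAnnotation(name=name, cpg_start=a, cpg_end=b))
    return out


def _strip_cpg(arr: np.ndarray, start: int, end: int) -> None:
    # remove every CG dinucleotide in [start, end) so only planted CpGs remain
    for i in range(start, end - 1):
        if arr[i] == "C" and arr[i + 1] == "G":
            arr[i + 1] = "A"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the toy genome, CpG index, guides, decoys, probes and regions."""
    rng = substream(config.seed, "reference")
    g = rng.choice(_BASES, size=config.genome_length)
    s0, e0 = config.island_span
    _strip_cpg(g, s0, e0)

    # non-overlapping CpG positions with a minimum gap of 2 (stars-and-bars)
    n = config.n_cpg_sites
    width = e0 - s0 - 1
    base = np.sort(rng.choice(width - (n - 1), size=n, replace=False))
    positions = s0 + base + np.arange(n)
    for p in positions:
        g[p], g[p + 1] = "C", "G"
    cpg_index = {i + 1: int(p) for i, p in enumerate(positions)}
    indexed_cells = set(positions) | set(positions + 1)

    guides, guide_loci = _place_guides(config, g, cpg_index, indexed_cells, rng)

    # verify the island invariant after PAM planting
    island_seq = "".join(g[s0:e0])
    found = {s0 + i for i in range(len(island_seq) - 1) if island_seq[i : i + 2] == "CG"}
    if found != set(int(p) for p in positions):
        raise AssertionError("island CpG index corrupted during guide planting")

    _plant_decoys(config, g, guides, rng)

    probes, gene_universe = _build_probes(config, cpg_index, guide_loci, guides, rng)

    return ReferenceBundle(
        genome="".join(g),
        chromosome="chrT",
        island=(s0, e0),
        cpg_index=cpg_index,
        guides=guides,
        guide_loci=guide_loci,
        probes=probes,
        regions=default_regions(config.n_cpg_sites),
        gene_universe=gene_universe,
    )


def _guide_anchor_sites(config: SimulationConfig) -> list[int]:
    if config.n_guides == 4:
        fracs = _GUIDE_ANCHOR_FRACTIONS_4
    else:
        fracs = np.linspace(0.25, 0.9, config.n_guides)
    return [min(config.n_cpg_sites, max(1, round(f * config.n_cpg_sites))) for f in fracs]


def _place_guides(config, g, cpg_index, indexed_cells, rng):
    """Plant NGG PAMs so each guide's protospacer reads straight off the genome.

    Each guide is anchored so that one indexed CpG lies 15-20 bp on its
    5'-upstream side; without such a witness site near the kernel edge the
    planted deposition radius would not be recoverable from clone data.
    """
    anchors = _guide_anchor_sites(config)
    strands = [_GUIDE_STRANDS_4[i % 4] if config.n_guides <= 4 else "+"
               for i in range(config.n_guides)]
    if config.n_guides == 4:
        strands = list(_GUIDE_STRANDS_4)
    guides: list[GuideRNA] = []
    loci: dict[str, tuple[int, int, str]] = {}
    taken: list[tuple[int, int]] = []

    for k in range(config.n_guides):
        gid = f"sg{k + 1}"
        strand = strands[k]
        placed = False
        for site_shift in (0, 1, -1, 2, -2, 3, -3):
            site = anchors[k] + site_shift
            if site not in cpg_index:
                continue
            a = cpg_index[site]
            for d in rng.permutation(np.arange(15, 21)):
                if strand == "+":
                    s = a + int(d)
                    pam_cells = (s + 20, s + 21, s + 22)
                else:
                    e = a - int(d) + 1
                    s = e - 20
                    pam_cells = (s - 3, s - 2, s - 1)
                lo, hi = min(s, pam_cells[0]), max(s + 20, pam_cells[-1] + 1)
                if lo < 0 or hi > config.genome_length:
                    continue
                if any(c in indexed_cells for c in pam_cells):
                    continue
                if any(not (hi <= t0 or lo >= t1) for t0, t1 in taken):
                    continue
                if strand == "+":
                    g[s + 20] = "A"  # PAM N, kept clear of creating a CpG
                    g[s + 21] = "G"
                    g[s + 22] = "G"
                    spacer = "".join(g[s : s + 20])
                else:
                    g[s - 3] = "C"
                    g[s - 2] = "C"
                    if g[s - 1] == "G":
                        g[s - 1] = "A"
                    spacer = _revcomp("".join(g[s : s + 20]))
                guides.append(GuideRNA(guide_id=gid, spacer=spacer))
                loci[gid] = (int(s), int(s + 20), strand)
                taken.append((lo, hi))
                placed = True
                break
            if placed:
                break
        if not placed:
            raise RuntimeError(f"could not place guide {gid}; island too crowded")
    return guides, loci


def _plant_decoys(config, g, guides, rng) -> None:
    """Plant near-match protospacer copies (with NGG PAM) outside the island."""
    s0, e0 = config.island_span
    margin = 100
    taken: list[tuple[int, int]] = [(s0 - margin, e0 + margin)]
    for guide in guides:
        for _ in range(config.n_decoys_per_guide):
            seq = list(guide.spacer)
            pos_mm = rng.choice(20, size=config.decoy_mismatches, replace=False)
            for j in pos_mm:
                alt = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alt[rng.integers(3)]
            site = "".join(seq) + "AGG"
            for _ in range(200):
                p = int(rng.integers(0, config.genome_length - 23))
                if all(p + 23 <= t0 or p >= t1 for t0, t1 in taken):
                    g[p : p + 23] = list(site)
                    taken.append((p, p + 23))
                    break


def _build_probes(config, cpg_index, guide_loci, guides, rng):
    """Probe manifest: target probes at guide-anchor CpGs, extra island probes
    far from every guide, and a scattered background on a second chromosome."""
    gene_universe = [config.target_gene]
    gene_universe += [f"INC{i + 1}" for i in range(config.n_incongruent_genes)]
    n_bg_genes = config.n_genes - len(gene_universe)
    gene_universe += [f"g{i + 1:04d}" for i in range(n_bg_genes)]

    probes: list[ProbeAnnotation] = []
    idx = 0

    def new_id():
        nonlocal idx
        idx += 1
        return f"cg{idx:08d}"

    intervals = list(guide_loci.values())
    # target probes: one at each guide's nearest upstream indexed CpG
    anchor_positions = []
    for gid, (s, e, strand) in guide_loci.items():
        ups = [p for p in cpg_index.values()
               if (strand == "+" and p < s and s - p <= config.deposition_radius)
               or (strand == "-" and p >= e and p - (e - 1) <= config.deposition_radius)]
        anchor_positions.append(min(ups, key=lambda p: min(abs(p - s), abs(p - e + 1)))
                                if ups else s)
    for i in range(config.n_target_probes):
        probes.append(ProbeAnnotation(
            probe_id=new_id(), chromosome="chrT",
            position=int(anchor_positions[i % len(anchor_positions)]),
            gene=config.target_gene, cpg_island=True))

    # island probes well away from every deposition kernel
    far = [p for p in cpg_index.values()
           if all(min(abs(p - s), abs(p - e + 1)) > 50 for s, e, _ in intervals)]
    rng.shuffle(far)
    for p in far[: config.n_island_extra_probes]:
        probes.append(ProbeAnnotation(
            probe_id=new_id(), chromosome="chrT", position=int(p),
            gene=config.target_gene, cpg_island=True))

    # planted incongruent probes (hyper-methylated, expression goes up)
    for i in range(config.n_incongruent_genes):
        probes.append(ProbeAnnotation(
            probe_id=new_id(), chromosome="chrB", position=1_000 * (i + 1),
            gene=f"INC{i + 1}", cpg_island=True))

    n_bg = config.n_probes - len(probes)
    bg_genes = gene_universe[1 + config.n_incongruent_genes :]
    for i in range(n_bg):
        gene = "" if rng.random() < 0.05 else bg_genes[int(rng.integers(len(bg_genes)))]
        probes.append(ProbeAnnotation(
            probe_id=new_id(), chromosome="chrB",
            position=100_000 + 500 * i, gene=gene,
            cpg_island=bool(rng.random() < config.background_island_fraction)))
    return probes, gene_universe


# ---------------------------------------------------------------------------
# methylation profiles and emissions

def simulate_methylation_profiles(
    ref: ReferenceBundle, config: SimulationConfig
) -> tuple[MethylationProfile, MethylationProfile]:
    """Control and treated per-CpG-site methylation probabilities.

    The treated profile elevates sites within ``deposition_radius`` bases of
    any protospacer edge, splitting the elevation ``upstream_bias`` to the
    guide's 5'-upstream side and ``1 - upstream_bias`` downstream. Sites
    beyond the radius, and sites inside the protospacer itself (occupied by
    the dCas9 footprint), keep their control probability.
    """
    rng = substream(config.seed, "profiles")
    control, treated = {}, {}
    for site, p in ref.cpg_index.items():
        base = float(np.clip(
            config.baseline_meth_prob
            + rng.uniform(-config.baseline_jitter, config.baseline_jitter),
            0.01, 0.3))
        control[site] = base
        w = 0.0
        for gid, (s, e, strand) in ref.guide_loci.items():
            d = signed_guide_distance(p, s, e, strand)
            if d is None or d == 0 or abs(d) > config.deposition_radius:
                continue
            w = max(w, config.upstream_bias if d < 0 else 1.0 - config.upstream_bias)
        treated[site] = base + w * (config.max_meth_prob - base) if w > 0 else base
    return (MethylationProfile("control", control),
            MethylationProfile("treated", treated))


def signed_guide_distance(pos: int, start: int, end: int, strand: str):
    """Base distance from a coordinate to the protospacer's nearest edge.

    Negative on the guide's 5'-upstream side, 0 inside the protospacer,
    positive downstream. ``end`` is exclusive.
    """
    if start <= pos < end:
        return 0
    if strand == "+":
        return pos - start if pos < start else pos - (end - 1)
    # '-' guide: upstream is the higher-coordinate side
    return -(pos - (end - 1)) if pos >= end else -(pos - start)


def sample_beta_matrix(ref, profiles, config):
    """Probes x samples beta matrix plus a sample sheet.

    Per-probe methylation level is mapped to the M scale, Gaussian noise of
    SD ``beta_noise_sd`` is added there (M-values are unbounded, so noise on
    this scale avoids boundary pile-up), and the result mapped back to (0,1).
    Designated target probes (and planted incongruent probes) are emitted at
    control M + ``delta_m_target`` so the planted group difference is
    centred exactly at the configured effect.
    """
    import pandas as pd

    rng = substream(config.seed, "betas")
    control, treated = profiles
    npg = config.n_samples_per_group
    samples = [f"ctrl_{i+1}" for i in range(npg)] + [f"trt_{i+1}" for i in range(npg)]
    groups = ["control"] * npg + ["treated"] * npg
    batches = [("a", "b")[i % 2] for i in range(npg)] * 2
    sheet = pd.DataFrame({"sample": samples, "group": groups, "batch": batches}
                         ).set_index("sample")

    target_ids = {p.probe_id for p in ref.probes[: config.n_target_probes]}
    incog_ids = {p.probe_id for p in ref.probes if p.gene.startswith("INC")}

    m = np.empty((len(ref.probes), 2 * npg))
    for i, probe in enumerate(ref.probes):
        if probe.probe_id in target_ids or probe.probe_id in incog_ids:
            pc = _footprint_prob(ref, control, probe, config)
            mc = beta_to_m(pc)
            mt = mc + config.delta_m_target
        elif probe.chromosome == ref.chromosome:
            mc = beta_to_m(_footprint_prob(ref, control, probe, config))
            mt = beta_to_m(_footprint_prob(ref, treated, probe, config))
        else:
            base = (rng.normal(-3.0, 1.0) if rng.random() < 0.7
                    else rng.normal(3.0, 1.0))
            mc = mt = base
        m[i, :npg] = mc
        m[i, npg:] = mt
    if config.beta_noise_sd > 0:
        m += rng.normal(0.0, config.beta_noise_sd, size=m.shape)
    betas = m_to_beta(m)
    mat = pd.DataFrame(betas, index=[p.probe_id for p in ref.probes], columns=samples)
    mat.index.name = "probe_id"
    return mat, sheet


def _footprint_prob(ref, profile, probe, config, half_width: int = 25) -> float:
    """Mean site probability over the probe's 50-bp footprint (island probes)."""
    ps = [profile.site_probabilities[n]
          for n, pos in ref.cpg_index.items()
          if abs(pos - probe.position) <= half_width]
    return float(np.mean(ps)) if ps else config.baseline_meth_prob


def sample_counts(ref, config):
    """Genes x samples negative-binomial count matrix plus sample sheet.

    Base means are log-normal; all genes share a common dispersion; the
    target gene is shifted by ``target_gene_log2fc`` in treated samples and
    each planted incongruent gene by ``incongruent_log2fc``.
    """
    import pandas as pd

    rng = substream(config.seed, "counts")
    genes = ref.gene_universe
    npg = config.n_rna_samples_per_group
    samples = [f"rna_ctrl_{i+1}" for i in range(npg)] + \
              [f"rna_trt_{i+1}" for i in range(npg)]
    groups = ["control"] * npg + ["treated"] * npg
    sheet = pd.DataFrame({"sample": samples, "group": groups,
                          "batch": [("a", "b")[i % 2] for i in range(npg)] * 2}
                         ).set_index("sample")

    base = rng.lognormal(np.log(config.count_base_mean), config.count_base_sigma,
                         size=len(genes))
    lfc = np.zeros(len(genes))
    for i, gene in enumerate(genes):
        if gene == config.target_gene:
            base[i] = config.target_gene_base_mean
            lfc[i] = config.target_gene_log2fc
        elif gene.startswith("INC"):
            base[i] = config.target_gene_base_mean  # planted construct, pinned
            lfc[i] = config.incongruent_log2fc

    mu = np.empty((len(genes), 2 * npg))
    mu[:, :npg] = base[:, None]
    mu[:, npg:] = (base * 2.0 ** lfc)[:, None]
    alpha = config.nb_dispersion
    if alpha <= 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    mat = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    mat.index.name = "gene"
    return mat, sheet


@dataclass
class CloneSet:
    region: RegionAnnotation
    condition: str
    reads: list[tuple[str, str]]  # (clone_id, sequence)
    truth: "object"  # DataFrame clones x CpG site numbers, values 0/1
    reference: RegionReference


def sample_clones(ref, profiles, region: RegionAnnotation, config,
                  condition: str = "treated") -> CloneSet:
    """Bisulfite-converted clone reads over one amplicon region.

    Per clone, per-site methylation states are independent Bernoulli draws
    from the profile, and the read is the amplicon reference passed through
    in-silico bisulfite conversion with those states.
    """
    import pandas as pd

    profile = profiles[0] if condition == "control" else profiles[1]
    regref = ref.region_reference(region)  # raises if region not in island
    rng = substream(config.seed, f"clones/{region.name}/{condition}")
    sites = sorted(regref.cpg_offsets)
    probs = np.array([profile.site_probabilities[n] for n in sites])

    reads, truth_rows, ids = [], [], []
    for c in range(config.n_clones_per_region):
        states = rng.random(len(sites)) < probs
        seq = bisulfite_convert(regref.sequence, states.tolist(),
                                config.bisulfite_conversion_rate, rng=rng,
                                cpg_offsets=[regref.cpg_offsets[n] for n in sites])
        cid = f"{condition[:2]}{c + 1:03d}_{region.name}"
        reads.append((cid, seq))
        truth_rows.append(states.astype(int))
        ids.append(cid)
    truth = pd.DataFrame(truth_rows, index=ids, columns=sites)
    truth.index.name = "clone_id"
    truth.columns.name = "cpg_site"
    return CloneSet(region=region, condition=condition, reads=reads,
                    truth=truth, reference=regref)
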