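"""Three-way congruence intersection and pipeline orchestration.

Combines the differential-methylation gene calls, the differential-
expression results and the guide-proximity records into one call per gene:
``on_target`` (hyper-methylated, congruently down-regulated, with a guide
site near a supporting probe), ``off_target_candidate`` (same molecular
evidence but no proximal guide site), ``incongruent`` (significant in both
assays but moving the same way — methylation up with expression up),
``methylation_only`` / ``expression_only``, or ``unaffected``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as maio
from .bisulfite import (call_cpg_methylation, composite_frequencies,
                        methylation_asymmetry, summarize_regions)
from .guidescan import find_sites, map_hits_to_probes
from .methylome import (ClassifierThresholds, beta_to_m, classify_probes,
                        collapse_to_genes, moderated_dm_test, per_probe_sd,
                        variance_filter)
from .simulate import (SimulationConfig, generate_reference, sample_beta_matrix,
                       sample_clones, sample_counts, simulate_methylation_profiles)
from .transcriptome import nb_wald_test, size_factors, estimate_dispersion

LABEL_ORDER = ["on_target", "off_target_candidate", "incongruent",
               "methylation_only", "expression_only", "unaffected"]


@dataclass
class PipelineConfig:
    """Everything one audit run needs, serializable to YAML/JSON."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    de_alpha: float = 0.05
    guide_window: int = 1000
    max_mismatch: int = 3
    include_batch: bool = False
    frequency_floor: float = 0.5
    sequential_dm: bool = True  # run the supervised test on variance-kept probes

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ClassifierThresholds(**d["thresholds"])
        return cls(**d)


def intersect_calls(dm_genes: pd.DataFrame, de: pd.DataFrame,
                    proximity, alpha_de: float = 0.05) -> pd.DataFrame:
    """One TargetCall per gene across all evidence sources.

    ``dm_genes`` is the candidate-gene table from :func:`collapse_to_genes`;
    ``de`` the Wald-test table indexed by gene; ``proximity`` an iterable of
    ProximityRecord. Guide proximity is evaluated against each gene's
    supporting candidate probes, not the gene body.
    """
    if de.index.duplicated().any():
        dup = de.index[de.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in DE input: {dup[:5]}")
    probe_hits: dict[str, list] = {}
    for rec in proximity:
        probe_hits.setdefault(rec.probe_id, []).append(rec)

    genes = sorted(set(dm_genes.index) | set(de.index))
    rows = []
    for gene in genes:
        dm_sig = gene in dm_genes.index
        direction = dm_genes.loc[gene, "direction"] if dm_sig else ""
        probes = dm_genes.loc[gene, "probes"].split(",") if dm_sig else []
        n_prox = sum(len(probe_hits.get(p, [])) for p in probes)
        prox_dist = min((r.distance for p in probes for r in probe_hits.get(p, [])),
                       default=np.nan)
        if gene in de.index:
            lfc = de.loc[gene, "log2fc"]
            p_adj_de = de.loc[gene, "p_adj"]
            de_sig = bool(p_adj_de < alpha_de) if not np.isnan(p_adj_de) else False
        else:
            lfc, p_adj_de, de_sig = np.nan, np.nan, False

        congruent = bool(dm_sig and de_sig and (
            (direction == "hyper" and lfc < 0) or (direction == "hypo" and lfc > 0)))
        congruent_dir = ("hyper_down" if congruent and direction == "hyper"
                         else "hypo_up" if congruent else "")

        if dm_sig and de_sig and congruent and n_prox > 0:
            label = "on_target"
        elif dm_sig and de_sig and congruent:
            label = "off_target_candidate"
        elif dm_sig and de_sig:
            label = "incongruent"
        elif dm_sig:
            label = "methylation_only"
        elif de_sig:
            label = "expression_only"
        else:
            label = "unaffected"
        rows.append({
            "gene": gene, "label": label, "congruent": congruent,
            "congruent_direction": congruent_dir,
            "dm_direction": direction,
            "n_dm_probes": len(probes), "dm_probes": ",".join(probes),
            "dm_min_p_adj": dm_genes.loc[gene, "min_p_adj"] if dm_sig else np.nan,
            "log2fc": lfc, "de_p_adj": p_adj_de,
            "n_proximal_hits": n_prox, "min_hit_distance": prox_dist,
        })
    out = pd.DataFrame(rows).set_index("gene")
    out["label"] = pd.Categorical(out["label"], categories=LABEL_ORDER, ordered=True)
    return out.sort_values(["label", "de_p_adj", "dm_min_p_adj", "gene"],
                           na_position="last")


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 write_clones: bool = True) -> dict:
    """Simulate inputs and execute the full audit; write tables and report.

    Stages: variance pre-filter -> moderated DM test (on the kept probes
    when ``sequential_dm``) -> BH -> classifier -> gene collapse; size
    factors -> dispersion -> NB Wald; guide scan -> probe proximity; then
    the three-way intersection. The JSON report records per-stage counts
    and every threshold used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim

    ref = generate_reference(sim)
    profiles = simulate_methylation_profiles(ref, sim)
    betas, sheet = sample_beta_matrix(ref, profiles, sim)
    counts, rna_sheet = sample_counts(ref, sim)

    # --- methylome arm
    m = pd.DataFrame(beta_to_m(betas.to_numpy()), index=betas.index,
                     columns=betas.columns)
    vf = variance_filter(m, config.thresholds.variance_sd_multiplier,
                         config.thresholds.sd_rule)
    m_dm = m.loc[vf.kept_probe_ids] if config.sequential_dm else m
    if len(m_dm) < 2:
        raise RuntimeError("variance filter left fewer than 2 probes")
    dm = moderated_dm_test(m_dm, sheet, include_batch=config.include_batch)
    classified = classify_probes(dm, m_dm, sheet, ref.probes, config.thresholds,
                                 sd_stats=vf.per_probe_sd)
    dm_genes = collapse_to_genes(classified, ref.probes)

    # --- transcriptome arm
    sf = size_factors(counts)
    disp = estimate_dispersion(counts, sf, rna_sheet)
    de = nb_wald_test(counts, rna_sheet, factors=sf, dispersions=disp)

    # --- guide arm
    hits = find_sites({ref.chromosome: ref.genome}, ref.guides, config.max_mismatch)
    proximity = map_hits_to_probes(hits, ref.probes, config.guide_window)

    calls = intersect_calls(dm_genes, de, proximity, config.de_alpha)

    # --- bisulfite arm (clone-level confirmation over the assay regions)
    clone_stats = {}
    regions = {r.name: r for r in ref.regions}
    for region_name, guide_id in (("region1", "sg4"), ("region2", "sg2")):
        if region_name not in regions:
            continue
        cs = sample_clones(ref, profiles, regions[region_name], sim, "treated")
        profs = [call_cpg_methylation(seq, cs.reference, cid) for cid, seq in cs.reads]
        comp = composite_frequencies(profs)
        asym = methylation_asymmetry(comp, guide_id, ref.guide_loci[guide_id],
                                     ref.cpg_index, config.frequency_floor)
        regsum = summarize_regions(comp, ref.regions, config.frequency_floor)
        clone_stats[region_name] = {
            "n_clones": comp.n_clones,
            "guide": guide_id,
            "upstream_fraction": _jsonify(asym.upstream_fraction),
            "radius_estimate_bp": _jsonify(asym.radius_estimate),
            "region_mean_frequencies": {
                r: _jsonify(v) for r, v in regsum["mean_frequency"].items()},
        }
        if write_clones:
            maio.write_fasta(outdir / f"clones_{region_name}.fa", cs.reads)
            maio.write_tsv(cs.truth, outdir / f"clones_{region_name}_truth.tsv")

    # --- outputs
    maio.write_fasta(outdir / "genome.fa", [(ref.chromosome, ref.genome)])
    maio.write_probe_manifest(outdir / "probes.tsv", ref.probes)
    maio.write_tsv(betas, outdir / "betas.tsv")
    maio.write_tsv(sheet.reset_index(), outdir / "samples.tsv", index=False)
    maio.write_tsv(counts, outdir / "counts.tsv")
    maio.write_tsv(rna_sheet.reset_index(), outdir / "rna_samples.tsv", index=False)
    maio.write_tsv(classified, outdir / "dm_probes.tsv")
    maio.write_tsv(dm_genes, outdir / "dm_genes.tsv")
    maio.write_tsv(de, outdir / "de_genes.tsv")
    maio.write_hits(outdir / "guide_hits.tsv", hits)
    maio.write_proximity(outdir / "guide_proximity.tsv", proximity)
    maio.write_tsv(calls, outdir / "target_calls.tsv")

    label_counts = calls["label"].value_counts().to_dict()
    sig_de = int((de["p_adj"] < config.de_alpha).sum())
    report = {
        "seed": sim.seed,
        "thresholds": {
            "alpha": config.thresholds.alpha,
            "variance_sd_multiplier": config.thresholds.variance_sd_multiplier,
            "delta_sd_multiplier": config.thresholds.delta_sd_multiplier,
            "control_m_max": config.thresholds.control_m_max,
            "treated_m_min": config.thresholds.treated_m_min,
            "sd_rule": config.thresholds.sd_rule,
            "de_alpha": config.de_alpha,
            "guide_window": config.guide_window,
            "max_mismatch": config.max_mismatch,
            "variance_threshold": _jsonify(vf.threshold),
            "delta_m_threshold": _jsonify(classified.attrs["delta_m_threshold"]),
        },
        "stages": {
            "probes_total": int(m.shape[0]),
            "probes_kept_variance": len(vf.kept_probe_ids),
            "probes_removed_variance": int(m.shape[0]) - len(vf.kept_probe_ids),
            "probes_dm_tested": int(m_dm.shape[0]),
            "probes_dm_significant": int((dm["p_adj"] < config.thresholds.alpha).sum()),
            "probes_candidate": int(classified["candidate"].sum()),
            "candidate_genes": int(dm_genes.shape[0]),
            "genes_total": int(counts.shape[0]),
            "genes_testable": int((de["status"] != "untestable").sum()),
            "genes_de_significant": sig_de,
            "guide_hits": len(hits),
            "proximity_records": len(proximity),
        },
        "eBayes": {"d0": _jsonify(dm.attrs["d0"]), "s0sq": _jsonify(dm.attrs["s0sq"])},
        "labels": {lab: int(label_counts.get(lab, 0)) for lab in LABEL_ORDER},
        "on_target_genes": calls.index[calls["label"] == "on_target"].tolist(),
        "clones": clone_stats,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _jsonify(x):
    if x is None:
        return None
    x = float(x)
    if np.isnan(x):
        return None
    if np.isinf(x):
        return "inf"
    return round(x, 10)
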