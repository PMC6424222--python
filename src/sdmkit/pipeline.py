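"""End-to-end orchestration: ingest -> polarize -> call -> annotate ->
spectra -> expectation -> tests, plus the bundled worked example that
re-derives the published TTA flow-proportion table from its printed counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import caller, contexts, expectation, io, spectra, stats

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str | None = None
    reference: str | None = None
    ancestral: str | None = None
    panel: str | None = None
    gff: str | None = None
    out_dir: str = "sdm_run"
    seed: int = 0
    enrichment_min_count: int = 150
    enrichment_min_log2: float = 0.3
    alpha: float = 0.05
    q_threshold: float = 0.05

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    polarized: list
    rejections: dict[str, int]
    callset: caller.CallSet
    snp_counts: dict
    paths: list
    path_flags: list
    observed_path_counts: dict
    obs_exp: list
    filter_cascade: dict[str, int] = field(default_factory=dict)


def snp_change_counts(
    polarized,
    anc_seq: io.AncestralSequence,
    gene_models: io.GeneModelSet | None = None,
    intergenic_only: bool = True,
) -> dict[contexts.ChangeKey, int]:
    """Triplet-context ChangeKey counts for isolated (non-paired) SNPs.

    Each noncoding SNP is recorded in all three frames; flanking bases come
    from the ancestral sequence and frames with low-confidence flanks are
    skipped.
    """
    positions = {(v.chrom, v.pos) for v in polarized}
    counts: dict[contexts.ChangeKey, int] = {}

    def lookup(chrom):
        def f(p):
            if not 0 <= p < len(anc_seq):
                return None
            if anc_seq.confidence(p) != "high":
                return None
            return anc_seq.base(p)

        return f

    for v in polarized:
        # isolated: no variant at either adjacent position
        if (v.chrom, v.pos - 1) in positions or (v.chrom, v.pos + 1) in positions:
            continue
        if intergenic_only and gene_models is not None and gene_models.is_coding(
            v.chrom, v.pos
        ):
            continue
        for key in contexts.triplet_records_for_snp(
            v.pos, v.anc_allele, v.der_allele, lookup(v.chrom)
        ):
            counts[key] = counts.get(key, 0) + 1
    return counts


def path_to_class(path: contexts.SDMPath) -> expectation.TripletPath:
    return expectation.TripletPath(
        path.ancestral,
        path.step1.pos,
        path.step1.derived,
        path.step2.pos,
        path.step2.derived,
    )


def analyze_cohort(
    variants,
    anc_seq: io.AncestralSequence,
    panel: io.PopulationPanel,
    gene_models: io.GeneModelSet | None = None,
) -> PipelineResult:
    """Run the full in-memory analysis on phased variants."""
    cascade: dict[str, int] = {"input_variants": len(variants)}
    anc_map = {v.chrom: anc_seq for v in variants}
    polarized, rejections = io.polarize_all(variants, anc_map)
    cascade["rejected_low_confidence"] = rejections.get("low_confidence", 0)
    cascade["rejected_mismatch"] = rejections.get("mismatch", 0)
    cascade["polarized"] = len(polarized)
    callset = caller.call_sdms(polarized, panel)
    cascade.update({f"pairs_{k}": v for k, v in callset.counts.items()})
    cascade["retained_sdm_pairs"] = callset.counts["SDM"]
    cascade["excluded_putative_mnps"] = callset.counts["MNP_candidate"]

    snp_counts = snp_change_counts(polarized, anc_seq, gene_models)

    paths = []
    flags = []
    for call in callset.calls:
        ps, fl = contexts.sdm_path_records(call, anc_seq, gene_models)
        paths.extend(ps)
        flags.extend(fl)

    noncoding = [p for p in paths if p.kind == "noncoding"]
    observed: dict[expectation.TripletPath, int] = {}
    for p in noncoding:
        key = path_to_class(p)
        observed[key] = observed.get(key, 0) + 1
    obs_exp = expectation.expected_sdm_counts(snp_counts, observed)
    return PipelineResult(
        polarized=polarized,
        rejections=rejections,
        callset=callset,
        snp_counts=snp_counts,
        paths=paths,
        path_flags=flags,
        observed_path_counts=observed,
        obs_exp=obs_exp,
        filter_cascade=cascade,
    )


def coupled_ratio(
    obs_exp: list[expectation.ObservedExpectedRecord],
    dinuc_core: tuple[str, str, str],
) -> float:
    """Observed/expected enrichment of one dinucleotide path.

    The expected counts are scaled so totals match, so a single strongly
    enriched path inflates the common scale and would bias its own ratio
    downward; the target's obs/exp is therefore normalized by the aggregate
    obs/exp of all other classes, which cancels the shared scale and returns
    the path's own enrichment.
    """
    target_obs = target_exp = 0.0
    rest_obs = rest_exp = 0.0
    for r in obs_exp:
        if not r.defined or not np.isfinite(r.expected):
            continue
        if r.path.dinuc_core == dinuc_core:
            target_obs += r.observed
            target_exp += r.expected
        else:
            rest_obs += r.observed
            rest_exp += r.expected
    if target_exp == 0 or rest_exp == 0 or rest_obs == 0:
        return float("nan")
    return (target_obs / target_exp) / (rest_obs / rest_exp)


def estimate_coupling(
    result: PipelineResult,
    anc_seq: io.AncestralSequence,
    gene_models: io.GeneModelSet | None,
    dinuc_core: tuple[str, str, str],
) -> float:
    """Estimate a dinucleotide path's enrichment with the rate conditional.

    Uses the abundance-weighted ("rate") expectation, under which a second
    mutation's hazard is proportional to the absolute mutability of the
    intermediate context, so the target's normalized obs/exp directly
    estimates any excess coupling of the two changes.
    """
    seq = {anc_seq.chrom: anc_seq.raw.upper()}
    if gene_models is not None:
        abundance = expectation.count_triplet_abundance(seq, gene_models).intergenic
    else:
        s = anc_seq.raw.upper()
        abundance = {}
        for i in range(len(s) - 2):
            t = s[i : i + 3]
            if all(b in "ACGT" for b in t):
                abundance[t] = abundance.get(t, 0) + 1
    obs_exp = expectation.expected_sdm_counts(
        result.snp_counts,
        result.observed_path_counts,
        mode="rate",
        triplet_abundance=abundance,
    )
    return coupled_ratio(obs_exp, dinuc_core)


def run(config: RunConfig) -> dict:
    """File-based pipeline run; returns a manifest of outputs and hashes."""
    for name in ("vcf", "reference", "ancestral", "panel"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"missing input: {name} ({path})")
    os.makedirs(config.out_dir, exist_ok=True)
    variants, skipped = io.read_phased_variants(config.vcf)
    anc = io.read_ancestral(config.ancestral)
    panel = io.read_panel(config.panel)
    gene_models = io.read_gene_models(config.gff) if config.gff else None
    chrom = variants[0].chrom if variants else next(iter(anc))
    result = analyze_cohort(variants, anc[chrom], panel, gene_models)
    result.filter_cascade["skipped_non_snv"] = skipped

    outputs = {}

    calls_path = os.path.join(config.out_dir, "calls.tsv")
    caller.calls_to_frame(result.callset, panel).to_csv(calls_path, sep="\t", index=False)
    outputs["calls"] = calls_path

    paths_path = os.path.join(config.out_dir, "paths.tsv")
    pd.DataFrame(
        {
            "path": [p.path_label for p in result.paths],
            "kind": [p.kind for p in result.paths],
            "anchor": [p.anchor for p in result.paths],
            "chrom": [p.chrom for p in result.paths],
            "pos": [p.pos + 1 for p in result.paths],
        }
    ).to_csv(paths_path, sep="\t", index=False)
    outputs["paths"] = paths_path

    oe_path = os.path.join(config.out_dir, "observed_expected.tsv")
    expectation.records_to_frame(result.obs_exp).to_csv(oe_path, sep="\t", index=False)
    outputs["observed_expected"] = oe_path

    cascade_path = os.path.join(config.out_dir, "filter_cascade.json")
    with open(cascade_path, "w") as fh:
        json.dump(result.filter_cascade, fh, indent=2)
    outputs["filter_cascade"] = cascade_path

    manifest = {
        "config": config.to_dict(),
        "outputs": {
            k: {"path": v, "sha256": _sha256(v)} for k, v in outputs.items()
        },
        "filter_cascade": result.filter_cascade,
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# bundled worked example: the TTA flow table
# ---------------------------------------------------------------------------


def load_tta_flow_counts() -> pd.DataFrame:
    """The bundled published counts of SDMs through intermediate TTA."""
    with resources.files("sdmkit.data").joinpath("table1_tta.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def worked_examples() -> dict:
    """Recompute the TTA flow proportions and dependence test from the
    bundled counts, checking every recomputed proportion against the printed
    value to 2 decimals.
    """
    df = load_tta_flow_counts()
    report: dict = {"checks": [], "failures": [], "headline": {}}
    for region, count_col, prop_col in (
        ("intergenic", "intergenic_sdms", "intergenic_prop"),
        ("intronic", "intronic_sdms", "intronic_prop"),
    ):
        flow = stats.FlowTable.from_counts(
            df.rename(columns={count_col: "count"})[["ancestral", "derived", "count"]],
            intermediate="TTA",
            region=region,
        )
        for _, row in df.iterrows():
            computed = flow.proportion(row["ancestral"], row["derived"])
            printed = float(row[prop_col])
            ok = abs(computed - printed) <= 0.005 + 1e-12
            entry = {
                "region": region,
                "ancestral": row["ancestral"],
                "derived": row["derived"],
                "computed": round(computed, 4),
                "printed": printed,
                "ok": ok,
            }
            report["checks"].append(entry)
            if not ok:
                report["failures"].append(entry)
        if region == "intergenic":
            inter_flow = flow
    report["headline"]["ttt_to_taa_intergenic"] = inter_flow.proportion("TTT", "TAA")
    report["headline"]["ttg_to_taa_intergenic"] = inter_flow.proportion("TTG", "TAA")
    chi2, p = stats.ancestral_dependence_test(inter_flow, "TTT", "TTG")
    report["ttt_vs_ttg_chi2"] = chi2
    report["ttt_vs_ttg_p"] = p
    report["n_checks"] = len(report["checks"])
    report["all_ok"] = not report["failures"]
    return report
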