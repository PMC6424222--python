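"""Synthetic phased cohorts with a known mutational ground truth.

The generator is deliberately coalescent-free: each polymorphism receives a
carrier set drawn from a discretized neutral (1/x) frequency spectrum with a
configurable bias toward its population of origin.  This keeps every planted
event exactly controllable and the whole generation instant, at the cost of
realistic linkage structure — which none of the counting and conditioning
analyses downstream depend on.

Three channels are planted:

* independent SNPs with triplet-context-dependent rates (CpG transitions
  elevated by a configurable multiplier, default 18x);
* MNPs: both derived alleles arise together on the same haplotypes (class
  weights enriched for GA->TT and GC->AA by default);
* SDMs: a second mutation placed adjacent to an existing one, with rate
  proportional to the SNP rate of that change in the *intermediate* sequence
  context times an optional coupling multiplier, and carriers restricted to a
  proper subset of the first event's carriers (so the intermediate haplotype
  exists and the planted order is well defined).

Every planted event is recorded in a ledger that round-trips through the
VCF writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AncestralSequence, GeneModelSet, PhasedVariant, PopulationPanel

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ca_cg_tg_coupling(multiplier: float) -> dict:
    """Coupling entries for the CA -> CG -> TG path and its reverse
    complement TG -> CG -> CA (strand-symmetric planting)."""
    return {("CA", "CG", "TG"): multiplier, ("TG", "CG", "CA"): multiplier}


@dataclass
class MutationModel:
    """Rates and biases of the synthetic cohort generator.

    Rates are per-site probabilities that a polymorphism of the given kind
    segregates in the cohort (a site-frequency model, not a per-generation
    mutation rate).
    """

    transition_rate: float = 0.008
    transversion_rate: float = 0.002  # per alternative base
    cpg_multiplier: float = 18.0
    sdm_scale: float = 0.4  # second-change channel scale
    coupling: dict = field(default_factory=dict)  # (anc,inter,der) dinucs -> mult
    mnp_rate: float = 3e-4
    mnp_enriched_prob: float = 0.6  # P(GA->TT | anc GA), P(GC->AA | anc GC)
    pop_bias: dict = field(default_factory=dict)  # pop -> {"C>T": mult, ...}
    origin_bias: float = 4.0  # carrier weight inside the origin population
    switch_error_rate: float = 0.0
    low_conf_fraction: float = 0.0
    ref_derived_fraction: float = 0.1

    def rate(self, b: str, d: str, left: str, right: str) -> float:
        r = self.transition_rate if (b, d) in TRANSITIONS else self.transversion_rate
        if b == "C" and d == "T" and right == "G":
            r *= self.cpg_multiplier
        if b == "G" and d == "A" and left == "C":
            r *= self.cpg_multiplier
        return r


@dataclass
class SyntheticCohort:
    chrom: str
    ancestral_raw: str  # case-encoded confidence
    reference: str
    positions: np.ndarray  # 0-based, sorted
    anc_bases: np.ndarray  # dtype '<U1'
    der_bases: np.ndarray
    haplotypes: np.ndarray  # n_variants x 2N, 1 = derived
    sample_ids: tuple[str, ...]
    panel: PopulationPanel
    gene_models: GeneModelSet
    ledger: pd.DataFrame
    genome_length: int

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def ancestral_sequence(self) -> AncestralSequence:
        return AncestralSequence(self.chrom, self.ancestral_raw)

    def to_phased_variants(self) -> list[PhasedVariant]:
        """Variants as they would be read back from the written VCF."""
        out = []
        for i, pos in enumerate(self.positions):
            anc, der = self.anc_bases[i], self.der_bases[i]
            ref = self.reference[pos]
            alt = der if ref == anc else anc
            hap = self.haplotypes[i]
            alleles = hap if ref == anc else (1 - hap)
            out.append(
                PhasedVariant(
                    chrom=self.chrom,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    haplotype_alleles=alleles.astype(np.int8),
                    sample_ids=self.sample_ids,
                )
            )
        return out


def _default_pop_bias(populations: tuple[str, ...]) -> dict:
    """Mildly divergent substitution-rate profiles per population.

    Each population over-produces a different transition type, echoing the
    divergent triplet spectra seen between human continental groups.
    """
    subs = ["C>T", "T>C", "A>G", "G>A", "C>A", "A>T"]
    bias = {}
    for i, pop in enumerate(populations):
        bias[pop] = {subs[i % len(subs)]: 2.0}
    return bias


def _make_genes(
    genome_length: int, n_genes: int, gene_length: int
) -> tuple[GeneModelSet, list[dict]]:
    models = GeneModelSet()
    specs = []
    if n_genes == 0:
        return models, specs
    spacing = genome_length // (n_genes + 1)
    for g in range(n_genes):
        start = spacing * (g + 1)
        end = start + gene_length
        if end + 2 >= genome_length:
            break
        strand = "+" if g % 2 == 0 else "-"
        tid = f"tx{g + 1}"
        models.add_transcript(tid, "1", strand, [(start, end)], phase=0)
        specs.append({"id": tid, "start": start, "end": end, "strand": strand})
    return models, specs


def generate(
    model: MutationModel,
    genome_length: int = 1_000_000,
    n_per_pop: int = 50,
    populations: tuple[str, ...] = ("AFR", "EUR", "EAS"),
    seed: int = 0,
    n_genes: int = 6,
    gene_length: int = 999,
    chrom: str = "1",
) -> SyntheticCohort:
    """Generate a phased cohort with planted SNPs, MNPs and SDMs."""
    if genome_length <= 10 or n_per_pop <= 0:
        raise ValueError("genome length and cohort size must be positive")
    rng = np.random.default_rng(seed)
    L = genome_length
    n_samples = n_per_pop * len(populations)
    n_hap = 2 * n_samples
    sample_ids = tuple(
        f"{pop}{i:04d}" for pop in populations for i in range(n_per_pop)
    )
    panel = PopulationPanel(
        pd.DataFrame(
            {
                "pop": [s[:3] for s in sample_ids],
                "super_pop": [s[:3] for s in sample_ids],
            },
            index=pd.Index(sample_ids, name="sample"),
        )
    )
    hap_pop = np.repeat([s[:3] for s in sample_ids], 2)

    seq = rng.choice(list(BASES), size=L, p=[0.29, 0.21, 0.21, 0.29])
    seq_str = "".join(seq)
    gene_models, gene_specs = _make_genes(L, n_genes, gene_length)

    pop_bias = model.pop_bias or _default_pop_bias(populations)

    # ---- first-round mutations -------------------------------------------
    events: dict[int, dict] = {}
    for b in BASES:
        base_mask = seq == b
        base_mask[:2] = base_mask[-2:] = False
        idx_all = np.nonzero(base_mask)[0]
        for d in BASES:
            if d == b:
                continue
            r = np.full(idx_all.shape, model.transition_rate
                        if (b, d) in TRANSITIONS else model.transversion_rate)
            if b == "C" and d == "T":
                r[seq[idx_all + 1] == "G"] *= model.cpg_multiplier
            if b == "G" and d == "A":
                r[seq[idx_all - 1] == "C"] *= model.cpg_multiplier
            hit = idx_all[rng.random(idx_all.shape) < np.minimum(r, 1.0)]
            for pos in hit:
                pos = int(pos)
                if pos in events:
                    if rng.random() < 0.5:
                        continue
                events[pos] = {"anc": b, "der": d, "type": "snp"}

    # frequency spectrum: P(k) ~ 1/k over 1..2N-1
    ks = np.arange(1, n_hap)
    k_probs = (1.0 / ks) / np.sum(1.0 / ks)

    pop_weight_vectors = {}
    for pop in populations:
        w = np.where(hap_pop == pop, model.origin_bias, 1.0)
        pop_weight_vectors[pop] = w / w.sum()

    def draw_carriers(origin_pop: str, k: int) -> np.ndarray:
        idx = rng.choice(n_hap, size=k, replace=False, p=pop_weight_vectors[origin_pop])
        mask = np.zeros(n_hap, dtype=np.int8)
        mask[idx] = 1
        return mask

    def choose_origin(sub: str) -> str:
        w = np.array([pop_bias.get(p, {}).get(sub, 1.0) for p in populations])
        return populations[rng.choice(len(populations), p=w / w.sum())]

    first_positions = sorted(events)
    k_draws = rng.choice(ks, size=len(first_positions), p=k_probs)
    for pos, k in zip(first_positions, k_draws):
        ev = events[pos]
        ev["origin"] = choose_origin(f"{ev['anc']}>{ev['der']}")
        ev["carriers"] = draw_carriers(ev["origin"], int(k))

    # ---- SDM channel ------------------------------------------------------
    sdm_pairs = []
    for pos in first_positions:
        ev = events[pos]
        k = int(ev["carriers"].sum())
        if k < 2:
            continue
        for side in (-1, 1):
            q = pos + side
            if q < 2 or q >= L - 2 or q in events:
                continue
            b = seq_str[q]
            left = ev["der"] if q - 1 == pos else seq_str[q - 1]
            right = ev["der"] if q + 1 == pos else seq_str[q + 1]
            lo = min(pos, q)
            anc_di = seq_str[lo] + seq_str[lo + 1]
            inter_di = (ev["der"] + seq_str[q]) if pos == lo else (seq_str[q] + ev["der"])
            for d in BASES:
                if d == b:
                    continue
                mult = model.coupling.get(
                    (
                        anc_di,
                        inter_di,
                        (ev["der"] + d) if pos == lo else (d + ev["der"]),
                    ),
                    1.0,
                )
                p2 = model.sdm_scale * model.rate(b, d, left, right) * mult
                if p2 > 1:
                    log.warning("second-change probability %.2f capped at 1", p2)
                    p2 = 1.0
                if rng.random() < p2:
                    carrier_idx = np.nonzero(ev["carriers"])[0]
                    u = int(rng.integers(1, k))  # proper nonempty subset
                    sub = rng.choice(carrier_idx, size=u, replace=False)
                    mask = np.zeros(n_hap, dtype=np.int8)
                    mask[sub] = 1
                    events[q] = {
                        "anc": b,
                        "der": d,
                        "type": "sdm_second",
                        "origin": ev["origin"],
                        "carriers": mask,
                        "partner": pos,
                    }
                    ev["type"] = "sdm_first"
                    sdm_pairs.append(
                        {
                            "pos1": lo,
                            "pos2": lo + 1,
                            "first_pos": pos,
                            "order": "left_first" if pos == lo else "right_first",
                            "origin": ev["origin"],
                        }
                    )
                    break  # one second change per side at most

    # ---- MNP channel ------------------------------------------------------
    mnp_pairs = []
    candidate = rng.random(L - 3) < model.mnp_rate
    for pos in np.nonzero(candidate)[0]:
        pos = int(pos)
        if pos < 2 or any(p in events for p in (pos, pos + 1)):
            continue
        a1, a2 = seq_str[pos], seq_str[pos + 1]
        der = None
        if a1 + a2 == "GA" and rng.random() < model.mnp_enriched_prob:
            der = "TT"
        elif a1 + a2 == "GC" and rng.random() < model.mnp_enriched_prob:
            der = "AA"
        if der is None:
            d1 = rng.choice([x for x in BASES if x != a1])
            d2 = rng.choice([x for x in BASES if x != a2])
            der = d1 + d2
        origin = populations[int(rng.integers(len(populations)))]
        k = int(rng.choice(ks, p=k_probs))
        mask = draw_carriers(origin, k)
        for off, (ab, db) in enumerate(zip(a1 + a2, der)):
            events[pos + off] = {
                "anc": ab,
                "der": db,
                "type": "mnp",
                "origin": origin,
                "carriers": mask,
                "partner": pos + (1 - off),
            }
        mnp_pairs.append({"pos1": pos, "pos2": pos + 1, "origin": origin})

    # ---- assemble ---------------------------------------------------------
    positions = np.array(sorted(events), dtype=np.int64)
    anc_bases = np.array([events[p]["anc"] for p in positions])
    der_bases = np.array([events[p]["der"] for p in positions])
    haplotypes = np.vstack([events[p]["carriers"] for p in positions]) if len(
        positions
    ) else np.zeros((0, n_hap), dtype=np.int8)

    reference = list(seq_str)
    for i, p in enumerate(positions):
        if rng.random() < model.ref_derived_fraction:
            reference[p] = der_bases[i]
    reference = "".join(reference)

    anc_raw = list(seq_str)
    if model.low_conf_fraction > 0:
        low = rng.random(L) < model.low_conf_fraction
        for p in np.nonzero(low)[0]:
            anc_raw[p] = anc_raw[p].lower()
    anc_raw = "".join(anc_raw)

    rows = []
    eid = 0
    paired = set()
    for rec in sdm_pairs:
        rows.append(
            {
                "event_id": eid,
                "type": "sdm",
                "pos1": rec["pos1"],
                "pos2": rec["pos2"],
                "anc": seq_str[rec["pos1"]] + seq_str[rec["pos1"] + 1],
                "der": events[rec["pos1"]]["der"] + events[rec["pos2"]]["der"],
                "order": rec["order"],
                "origin_pop": rec["origin"],
                "n_carriers": int(
                    (events[rec["pos1"]]["carriers"] & events[rec["pos2"]]["carriers"]).sum()
                ),
            }
        )
        paired.update((rec["pos1"], rec["pos2"]))
        eid += 1
    for rec in mnp_pairs:
        rows.append(
            {
                "event_id": eid,
                "type": "mnp",
                "pos1": rec["pos1"],
                "pos2": rec["pos2"],
                "anc": seq_str[rec["pos1"]] + seq_str[rec["pos1"] + 1],
                "der": events[rec["pos1"]]["der"] + events[rec["pos2"]]["der"],
                "order": "",
                "origin_pop": rec["origin"],
                "n_carriers": int(events[rec["pos1"]]["carriers"].sum()),
            }
        )
        paired.update((rec["pos1"], rec["pos2"]))
        eid += 1
    for p in positions:
        if int(p) in paired:
            continue
        ev = events[int(p)]
        rows.append(
            {
                "event_id": eid,
                "type": "snp",
                "pos1": int(p),
                "pos2": -1,
                "anc": ev["anc"],
                "der": ev["der"],
                "order": "",
                "origin_pop": ev["origin"],
                "n_carriers": int(ev["carriers"].sum()),
            }
        )
        eid += 1
    ledger = pd.DataFrame(
        rows,
        columns=["event_id", "type", "pos1", "pos2", "anc", "der", "order",
                 "origin_pop", "n_carriers"],
    )

    return SyntheticCohort(
        chrom=chrom,
        ancestral_raw=anc_raw,
        reference=reference,
        positions=positions,
        anc_bases=anc_bases,
        der_bases=der_bases,
        haplotypes=haplotypes,
        sample_ids=sample_ids,
        panel=panel,
        gene_models=gene_models,
        ledger=ledger,
        genome_length=L,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_fasta(path: str, chrom: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> dict[str, str]:
    """Write VCF, reference/ancestral FASTA, GFF3, panel and ledger TSVs."""
    import os

    from .io import write_phased_variants

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "reference": os.path.join(out_dir, "reference.fa"),
        "ancestral": os.path.join(out_dir, "ancestral.fa"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "panel": os.path.join(out_dir, "panel.tsv"),
        "ledger": os.path.join(out_dir, "ledger.tsv"),
    }
    write_phased_variants(
        cohort.to_phased_variants(),
        paths["vcf"],
        {cohort.chrom: cohort.genome_length},
        sample_ids=cohort.sample_ids,
    )
    _write_fasta(paths["reference"], cohort.chrom, cohort.reference)
    _write_fasta(paths["ancestral"], cohort.chrom, cohort.ancestral_raw)
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, info in sorted(cohort.gene_models.transcripts.items()):
            for start, end in info["intervals"]:
                fh.write(
                    "\t".join(
                        [
                            info["chrom"], "sdmkit", "CDS", str(start + 1), str(end),
                            ".", info["strand"], "0", f"ID=cds_{tid};Parent={tid}",
                        ]
                    )
                    + "\n"
                )
    cohort.panel.table.reset_index().to_csv(paths["panel"], sep="\t", index=False)
    cohort.ledger.to_csv(paths["ledger"], sep="\t", index=False)
    return paths


def inject_switch_errors(
    cohort: SyntheticCohort, rate: float, seed: int = 0
) -> SyntheticCohort:
    """Flip downstream phase at heterozygous sites with the given probability.

    The ledger keeps the true phase; only the haplotype matrix changes.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or len(cohort.positions) == 0:
        return cohort
    rng = np.random.default_rng(seed)
    hap = cohort.haplotypes.copy()
    n_samples = len(cohort.sample_ids)
    for s in range(n_samples):
        a, b = hap[:, 2 * s], hap[:, 2 * s + 1]
        het = np.nonzero(a != b)[0]  # variant indices, position-sorted
        flipped = False
        for vi in het:
            if rng.random() < rate:
                flipped = not flipped
            if flipped:
                a[vi], b[vi] = b[vi], a[vi]
    return replace(cohort, haplotypes=hap)
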