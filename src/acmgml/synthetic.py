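"""Synthetic annotated-variant generator for fully offline testing.

Real BRCA1/2 interpretation pipelines depend on closed clinical databases;
this module emulates their tabular extracts.  Annotation fields are sampled
*backward* from target evidence patterns — each generated variant is built
to trigger an intended set of criteria, then verified against the engine —
so the generated files, the evidence vectors and the class labels agree by
construction.

Class labels derive from an additive evidence score mirroring the
conventional ACMG strength hierarchy (very strong +8, strong +4, moderate
+2, supporting +1 on the pathogenic side; stand-alone -8, strong -4,
supporting -1 on the benign side).  A variant scores into the pathogenic
band above +6, the benign band below -4, uncertain in between; a
configurable label-noise rate emulates inter-interpreter disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import CriterionVector, EngineConfig, build_criterion_vector
from .io_annotation import (AnnotatedVariant, ClinVarRecord, ClinVarReference,
                            CRITERIA_ORDER, IntervalSet, LabeledDataset,
                            VariantKey, variant_span)

log = logging.getLogger(__name__)

DEFAULT_EVIDENCE_WEIGHTS: dict[str, int] = {
    "PVS1": 8, "PS1": 4, "PS4": 4, "PM1": 2, "PM2": 2, "PM4": 2, "PM5": 2,
    "PP2": 1, "PP3": 1, "PP5": 1,
    "BA1": -8, "BS1": -4, "BP1": -1, "BP3": -1, "BP4": -1, "BP6": -1, "BP7": -1,
}

#: GRCh37 gene bodies used to draw plausible positions
GENE_SPANS = {"BRCA1": ("17", 41_196_312, 41_277_500),
              "BRCA2": ("13", 32_889_617, 32_973_809)}

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    The default class mixture 173:130:194 (P/LP : VUS : B/LB over 497
    variants) matches the labeled cohort the classifiers were designed
    around.
    """

    n_variants: int = 497
    class_weights: tuple[float, float, float] = (173.0, 130.0, 194.0)  # P/LP, VUS, B/LB
    label_noise_rate: float = 0.0
    seed: int = 0
    evidence_weights: dict = field(default_factory=lambda: dict(DEFAULT_EVIDENCE_WEIGHTS))
    pathogenic_cut: int = 6
    benign_cut: int = -4

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise_rate < 1.0:
            raise ValueError("label_noise_rate must be in [0,1)")
        if not self.benign_cut < 0 < self.pathogenic_cut:
            raise ValueError("cuts must satisfy benign_cut < 0 < pathogenic_cut")

    def mixture(self) -> np.ndarray:
        w = np.asarray(self.class_weights, dtype=float)
        return w / w.sum()


def evidence_score(vector: CriterionVector,
                   weights: dict[str, int] = DEFAULT_EVIDENCE_WEIGHTS) -> int:
    return sum(weights[name] * getattr(vector, name) for name in CRITERIA_ORDER)


def score_to_label(score: int, cfg: SyntheticConfig) -> str:
    if score > cfg.pathogenic_cut:
        return "P/LP"
    if score < cfg.benign_cut:
        return "B/LB"
    return "VUS"


# ---------------------------------------------------------------------------
# evidence patterns, grouped by the class band their score falls in

PATTERNS: dict[str, list[frozenset]] = {
    "P/LP": [
        frozenset({"PVS1", "PM2"}),                    # +10
        frozenset({"PVS1", "PM2", "PP5"}),             # +11
        frozenset({"PVS1", "PP3", "PM2"}),             # +11
        frozenset({"PS1", "PM2", "PP5"}),              # +7
        frozenset({"PVS1", "PS4", "PM2"}),             # +14
        frozenset({"PS4", "PM2", "PP3"}),              # +7
        frozenset({"PVS1"}),                           # +8
        frozenset({"PVS1", "PM4", "PM2"}),             # +12 (stop-loss)
    ],
    "VUS": [
        frozenset(),                                   # 0
        frozenset({"PM2"}),                            # +2
        frozenset({"PM2", "PP3"}),                     # +3
        frozenset({"PP3"}),                            # +1
        frozenset({"BP4"}),                            # -1
        frozenset({"PM4", "PM2"}),                     # +4
        frozenset({"PM5", "PM2"}),                     # +4
        frozenset({"BP4", "BP7"}),                     # -2
        frozenset({"PS1", "PM2"}),                     # +6 (boundary)
        frozenset({"BS1", "PP3"}),                     # -3
        frozenset({"PS4"}),                            # +4
    ],
    "B/LB": [
        frozenset({"BA1", "BS1"}),                     # -12
        frozenset({"BA1", "BS1", "BP4", "BP6"}),       # -14
        frozenset({"BS1", "BP4", "BP6"}),              # -6
        frozenset({"BS1", "BP6"}),                     # -5
        frozenset({"BS1", "BP4"}),                     # -5
        frozenset({"BS1", "BP3", "BP4"}),              # -6
        frozenset({"BA1", "BS1", "BP4", "BP7"}),       # -14
        frozenset({"BS1", "BP6", "BP4", "BP7"}),       # -7
    ],
}


@dataclass
class _Realized:
    variant: AnnotatedVariant
    pattern: frozenset
    clinvar_rows: list[ClinVarRecord]
    repeat_interval: tuple[str, int, int] | None
    raw_alleles: tuple[int, str, str]      # pre-normalization (pos, ref, alt)


class _Allocator:
    """Deterministic, collision-free genomic and codon coordinates."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.next_pos = {g: span[1] for g, span in GENE_SPANS.items()}
        self.next_codon = 100

    def position(self, gene: str) -> int:
        pos = self.next_pos[gene]
        self.next_pos[gene] = pos + int(self.rng.integers(60, 200))
        return pos

    def codon(self) -> int:
        codon = self.next_codon
        self.next_codon += int(self.rng.integers(1, 4))
        return codon


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return ref, alt


def realize_pattern(pattern: frozenset, gene: str, alloc: _Allocator,
                    rng: np.random.Generator) -> _Realized:
    """Construct one annotated variant whose engine vector equals ``pattern``.

    Field values are drawn inside the region of annotation space that the
    target criteria require (and everything else outside its triggering
    region), so engine/generator agreement holds by construction.
    """
    chrom = GENE_SPANS[gene][0]
    pos = alloc.position(gene)
    clinvar_rows: list[ClinVarRecord] = []
    repeat_iv = None

    # consequence
    if "BP7" in pattern:
        consequence = "synonymous"
    elif "BP3" in pattern:
        consequence = "inframe_insertion" if rng.random() < 0.5 else "inframe_deletion"
    elif "PVS1" in pattern and "PM4" in pattern:
        consequence = "stop_lost"
    elif "PM4" in pattern:
        consequence = "inframe_insertion" if rng.random() < 0.5 else "inframe_deletion"
    elif "PVS1" in pattern:
        consequence = ("frameshift", "stop_gained", "splice_donor",
                       "splice_acceptor")[rng.integers(4)]
    else:
        consequence = "missense"

    # alleles
    if consequence == "inframe_deletion":
        anchor = _BASES[rng.integers(4)]
        deleted = "".join(_BASES[rng.integers(4)] for _ in range(3))
        raw = (pos, anchor + deleted, anchor)
    elif consequence == "inframe_insertion":
        anchor = _BASES[rng.integers(4)]
        inserted = "".join(_BASES[rng.integers(4)] for _ in range(3))
        raw = (pos, anchor, anchor + inserted)
    elif consequence == "frameshift":
        anchor = _BASES[rng.integers(4)]
        raw = (pos, anchor + _BASES[rng.integers(4)], anchor)
    else:
        ref, alt = _snv(rng)
        raw = (pos, ref, alt)
    key = VariantKey.make(chrom, *raw)

    fields: dict = {"consequence": consequence}

    # exon / codon context (never the BRCA2 terminal exon, so PVS1 holds)
    exon_total = 23 if gene == "BRCA1" else 27
    fields["exon_index"] = int(rng.integers(2, exon_total - 1))
    fields["exon_total"] = exon_total
    codon = alloc.codon()
    if consequence in ("missense", "stop_gained", "stop_lost", "synonymous",
                       "frameshift", "inframe_insertion", "inframe_deletion"):
        fields["protein_position"] = codon
        fields["cds_position"] = codon * 3 - 1
    if consequence == "missense":
        aa_ref = _AA[rng.integers(20)]
        aa_alt = _AA[(_AA.index(aa_ref) + rng.integers(1, 20)) % 20]
        fields["aa_ref"], fields["aa_alt"] = aa_ref, aa_alt
        fields["given_ref"] = key.ref or None

    # population frequency
    if "BA1" in pattern:
        af = float(rng.uniform(0.051, 0.3))
    elif "BS1" in pattern:
        af = float(rng.uniform(0.0101, 0.0499))
    elif "PM2" in pattern:
        af = None
    else:
        af = float(rng.uniform(1e-5, 0.009))
    if af is not None:
        which = rng.integers(3)
        if which in (0, 2):
            fields["af_gnomad_noncancer"] = round(af, 6)
        if which in (1, 2):
            fields["af_exac_nontcga"] = round(min(af, 0.9999), 6)

    # case-control counts
    if "PS4" in pattern:
        ac_case = int(rng.integers(5, 12))
        fields.update(ac_case=ac_case, an_case=1000,
                      ac_control=int(rng.integers(0, 6)), an_control=100000)

    # in-silico scores
    if "PP3" in pattern:
        fields.update(metasvm_pred="deleterious", condel_pred="deleterious",
                      gerp_rs=round(float(rng.uniform(2.5, 6.0)), 3),
                      ada_score=round(float(rng.uniform(0.7, 1.0)), 3),
                      rf_score=round(float(rng.uniform(0.7, 1.0)), 3))
    elif "BP7" in pattern:
        fields["gerp_rs"] = round(float(rng.uniform(-3.0, 1.9)), 3)
        if rng.random() < 0.5:
            fields["ada_score"] = round(float(rng.uniform(0.0, 0.59)), 3)
            fields["rf_score"] = round(float(rng.uniform(0.0, 0.59)), 3)
    elif "BP4" in pattern:
        fields["gerp_rs"] = round(float(rng.uniform(-3.0, 1.9)), 3)

    # ClinVar records
    transcript = key.transcript
    if "PS1" in pattern:
        # same amino-acid change via a different nucleotide change
        ref2, alt2 = _snv(rng)
        clinvar_rows.append(ClinVarRecord(
            key=VariantKey.make(chrom, pos + 1, ref2, alt2),
            protein_position=fields["protein_position"],
            aa_ref=fields["aa_ref"], aa_alt=fields["aa_alt"], significance="P"))
        fields["mmsplice_pathogenicity"] = round(float(rng.uniform(0.0, 0.5)), 3)
    if "PM5" in pattern:
        other_alt = _AA[(_AA.index(fields["aa_alt"]) + 3) % 20]
        if other_alt == fields["aa_ref"]:
            other_alt = _AA[(_AA.index(fields["aa_alt"]) + 4) % 20]
        ref2, alt2 = _snv(rng)
        clinvar_rows.append(ClinVarRecord(
            key=VariantKey.make(chrom, pos + 2, ref2, alt2),
            protein_position=fields["protein_position"],
            aa_ref=fields["aa_ref"], aa_alt=other_alt, significance="P"))
        fields["mmsplice_pathogenicity"] = round(float(rng.uniform(0.0, 0.5)), 3)
    if "PP5" in pattern or "BP6" in pattern:
        sig = ("P", "LP")[rng.integers(2)] if "PP5" in pattern else ("B", "LB")[rng.integers(2)]
        clinvar_rows.append(ClinVarRecord(
            key=key, protein_position=fields.get("protein_position"),
            aa_ref=fields.get("aa_ref"), aa_alt=fields.get("aa_alt"),
            significance=sig))
        fields["clinvar_significance"] = sig
        fields["clinvar_review_stars"] = int(rng.integers(2, 5))

    # repeat context
    if "BP3" in pattern:
        start, end = variant_span(key)
        repeat_iv = (chrom, start - int(rng.integers(0, 5)),
                     end + int(rng.integers(1, 10)))
        fields["in_repeat_region"] = True

    variant = AnnotatedVariant(key=key, **fields)
    variant.validate()
    return _Realized(variant=variant, pattern=pattern,
                     clinvar_rows=clinvar_rows,
                     repeat_interval=repeat_iv, raw_alleles=raw)


# ---------------------------------------------------------------------------
# fixture bank

@dataclass
class FixtureBank:
    """Hand-designed (variant, expected-vector) pairs covering every rule
    branch, each threshold probed at, just below and just above its value."""

    entries: list[tuple[str, AnnotatedVariant, CriterionVector]]
    clinvar: ClinVarReference

    def __len__(self) -> int:
        return len(self.entries)


def generate_fixture_bank(cfg: EngineConfig | None = None) -> FixtureBank:
    cfg = cfg or EngineConfig()
    clinvar = ClinVarReference()
    entries: list[tuple[str, AnnotatedVariant, CriterionVector]] = []

    def key17(pos, ref="A", alt="G"):
        return VariantKey.make("17", pos, ref, alt)

    def key13(pos, ref="A", alt="G"):
        return VariantKey.make("13", pos, ref, alt)

    def add(name, variant, **flags):
        variant.validate()
        entries.append((name, variant, CriterionVector(**flags)))

    V = AnnotatedVariant

    # frequency thresholds (strict > at both cutoffs)
    for i, (af, ba1, bs1) in enumerate([(0.049, 0, 1), (0.05, 0, 1), (0.051, 1, 1)]):
        add(f"ba1_boundary_{af}", V(key17(41_200_000 + i), consequence="missense",
                                    af_gnomad_noncancer=af), BA1=ba1, BS1=bs1)
    for i, (af, bs1) in enumerate([(0.009, 0), (0.01, 0), (0.011, 1)]):
        add(f"bs1_boundary_{af}", V(key17(41_200_010 + i), consequence="missense",
                                    af_exac_nontcga=af), BS1=bs1)
    add("pm2_both_absent", V(key17(41_200_020), consequence="missense"), PM2=1)
    add("pm2_zero_af", V(key17(41_200_021), consequence="missense",
                         af_gnomad_noncancer=0.0, af_exac_nontcga=0.0), PM2=1)
    add("no_pm2_tiny_af", V(key17(41_200_022), consequence="missense",
                            af_gnomad_noncancer=1e-6))

    # PVS1 and the BRCA2 terminal-exon exception
    add("pvs1_brca1_stop", V(key17(41_200_030), consequence="stop_gained",
                             protein_position=100), PVS1=1, PM2=1)
    add("pvs1_missense_no", V(key17(41_200_031), consequence="missense"), PM2=1)
    b = cfg.brca2_terminal_codon_boundary
    add("pvs1_brca2_last_exon_at_boundary",
        V(key13(32_900_000), consequence="stop_gained", exon_index=27,
          exon_total=27, protein_position=b, af_gnomad_noncancer=1e-5), PVS1=1)
    add("pvs1_brca2_last_exon_past_boundary",
        V(key13(32_900_001), consequence="stop_gained", exon_index=27,
          exon_total=27, protein_position=b + 1, af_gnomad_noncancer=1e-5))
    add("pvs1_brca2_not_last_exon",
        V(key13(32_900_002), consequence="stop_gained", exon_index=10,
          exon_total=27, protein_position=b + 1, af_gnomad_noncancer=1e-5), PVS1=1)

    # PP3/BP4: GERP and splice-score boundaries (strict >)
    insilico = dict(metasvm_pred="deleterious", condel_pred="deleterious",
                    ada_score=0.9, rf_score=0.9, af_gnomad_noncancer=1e-5)
    for i, (gerp, pp3) in enumerate([(1.9, 0), (2.0, 0), (2.1, 1)]):
        add(f"pp3_gerp_boundary_{gerp}",
            V(key17(41_200_040 + i), consequence="missense", gerp_rs=gerp, **insilico),
            PP3=pp3, BP4=1 - pp3)
    for i, (ada, pp3) in enumerate([(0.59, 0), (0.6, 0), (0.61, 1)]):
        add(f"pp3_ada_boundary_{ada}",
            V(key17(41_200_050 + i), consequence="missense", gerp_rs=3.0,
              metasvm_pred="deleterious", condel_pred="deleterious",
              ada_score=ada, rf_score=0.9, af_gnomad_noncancer=1e-5),
            PP3=pp3, BP4=1 - pp3)
    add("pp3_no_scores", V(key17(41_200_060), consequence="missense",
                           af_gnomad_noncancer=1e-5))
    add("bp4_single_benign_score", V(key17(41_200_061), consequence="missense",
                                     gerp_rs=1.0, af_gnomad_noncancer=1e-5), BP4=1)

    # PS1/PM5 with the MMSplice gate probed around its threshold
    ps1_codon = 1699
    clinvar.add(ClinVarRecord(key=key17(41_215_000, "G", "T"),
                              protein_position=ps1_codon, aa_ref="R", aa_alt="W",
                              significance="P"))
    m = cfg.mmsplice_threshold
    for i, (mm, ps1) in enumerate([(m - 0.01, 1), (m, 0), (m + 0.01, 0)]):
        add(f"ps1_mmsplice_gate_{round(mm, 3)}",
            V(key17(41_215_100 + i, "C", "T"), consequence="missense",
              protein_position=ps1_codon, aa_ref="R", aa_alt="W",
              mmsplice_pathogenicity=mm, af_gnomad_noncancer=1e-5), PS1=ps1)
    add("ps1_mmsplice_absent_permissive",
        V(key17(41_215_110, "C", "G"), consequence="missense",
          protein_position=ps1_codon, aa_ref="R", aa_alt="W",
          af_gnomad_noncancer=1e-5), PS1=1)
    add("pm5_different_substitution",
        V(key17(41_215_120, "C", "A"), consequence="missense",
          protein_position=ps1_codon, aa_ref="R", aa_alt="Q",
          mmsplice_pathogenicity=0.1, af_gnomad_noncancer=1e-5), PM5=1)
    add("ps1_pm5_no_codon_record",
        V(key17(41_215_130, "C", "A"), consequence="missense",
          protein_position=77, aa_ref="R", aa_alt="Q",
          mmsplice_pathogenicity=0.1, af_gnomad_noncancer=1e-5))

    # PP5/BP6 exact-key lookups (reference is pre-filtered for admissibility)
    clinvar.add(ClinVarRecord(key=key17(41_216_000), protein_position=None,
                              aa_ref=None, aa_alt=None, significance="LP"))
    clinvar.add(ClinVarRecord(key=key17(41_216_001), protein_position=None,
                              aa_ref=None, aa_alt=None, significance="B"))
    clinvar.add(ClinVarRecord(key=key17(41_216_002), protein_position=None,
                              aa_ref=None, aa_alt=None, significance="VUS"))
    add("pp5_lp_record", V(key17(41_216_000), consequence="missense",
                           af_gnomad_noncancer=1e-5), PP5=1)
    add("bp6_b_record", V(key17(41_216_001), consequence="missense",
                          af_gnomad_noncancer=1e-5), BP6=1)
    add("vus_record_neither", V(key17(41_216_002), consequence="missense",
                                af_gnomad_noncancer=1e-5))

    # BP7 (synonymous only; splice scores low-or-absent, conservation low)
    add("bp7_low_everything", V(key17(41_217_000), consequence="synonymous",
                                ada_score=0.1, rf_score=0.1, gerp_rs=1.5,
                                af_gnomad_noncancer=1e-5), BP7=1, BP4=1)
    add("bp7_ada_high", V(key17(41_217_001), consequence="synonymous",
                          ada_score=0.7, rf_score=0.1, gerp_rs=1.5,
                          af_gnomad_noncancer=1e-5), BP4=1)
    add("bp7_scores_absent_ok", V(key17(41_217_002), consequence="synonymous",
                                  gerp_rs=1.5, af_gnomad_noncancer=1e-5),
        BP7=1, BP4=1)
    add("bp7_gerp_absent_blocks", V(key17(41_217_003), consequence="synonymous",
                                    ada_score=0.1, rf_score=0.1,
                                    af_gnomad_noncancer=1e-5), BP4=1)
    add("bp7_gerp_at_threshold", V(key17(41_217_004), consequence="synonymous",
                                   gerp_rs=2.0, af_gnomad_noncancer=1e-5), BP4=1)
    add("bp7_missense_gate", V(key17(41_217_005), consequence="missense",
                               ada_score=0.1, rf_score=0.1, gerp_rs=1.5,
                               af_gnomad_noncancer=1e-5), BP4=1)

    # PM4/BP3 and repeat context
    add("pm4_inframe_nonrepeat", V(key17(41_218_000, "ACTG", "A"),
                                   consequence="inframe_deletion",
                                   af_gnomad_noncancer=1e-5), PM4=1)
    add("bp3_inframe_repeat", V(key17(41_218_010, "ACTG", "A"),
                                consequence="inframe_deletion",
                                in_repeat_region=True,
                                af_gnomad_noncancer=1e-5), BP3=1)
    add("pm4_stop_lost_repeat", V(key17(41_218_020), consequence="stop_lost",
                                  in_repeat_region=True,
                                  af_gnomad_noncancer=1e-5), PM4=1, PVS1=1)

    # PS4 case-control enrichment
    add("ps4_enriched", V(key17(41_219_000), consequence="missense",
                          ac_case=6, an_case=1000, ac_control=5,
                          an_control=100000, af_gnomad_noncancer=1e-5), PS4=1)
    add("ps4_or_too_low", V(key17(41_219_001), consequence="missense",
                            ac_case=1, an_case=1000, ac_control=100,
                            an_control=100000, af_gnomad_noncancer=1e-5))
    add("ps4_not_significant", V(key17(41_219_002), consequence="missense",
                                 ac_case=1, an_case=50, ac_control=2,
                                 an_control=500, af_gnomad_noncancer=1e-5))
    add("ps4_counts_absent", V(key17(41_219_003), consequence="missense",
                               af_gnomad_noncancer=1e-5))

    # compound patterns
    add("all_absent", V(key17(41_220_000), consequence="other"), PM2=1)
    clinvar.add(ClinVarRecord(key=key17(41_220_001, "AG", "A"),
                              protein_position=None, aa_ref=None, aa_alt=None,
                              significance="P"))
    add("frameshift_absent_clinvar_p", V(key17(41_220_001, "AG", "A"),
                                         consequence="frameshift"),
        PVS1=1, PM2=1, PP5=1)

    return FixtureBank(entries=entries, clinvar=clinvar)


# ---------------------------------------------------------------------------
# worked-example confusion matrices

def reference_confusion_fixtures() -> list[dict]:
    """Two worked-example test-set confusion matrices for the serial scheme,
    with their published per-class metric values (display-rounded).

    Used as ground truth by the metrics tests: recomputing every metric
    from the matrix must reproduce the tabulated values.
    """
    return [
        {
            "name": "tier1_vus_vs_other",
            "class_order": ["other", "VUS"],
            # rows = truth, cols = prediction
            "confusion": np.array([[64, 8], [0, 28]]),
            "accuracy": 0.92,
            "per_class": {
                "other": {"precision": 1.00, "recall": 0.89,
                          "specificity": 1.00, "f1": 0.94, "support": 72},
                "VUS": {"precision": 0.78, "recall": 1.00,
                        "specificity": 0.89, "f1": 0.88, "support": 28},
            },
            "weighted": {"precision": 0.94, "recall": 0.92, "f1": 0.92},
        },
        {
            "name": "tier2_blb_vs_plp",
            "class_order": ["B/LB", "P/LP"],
            "confusion": np.array([[36, 0], [1, 37]]),
            "accuracy": 0.99,
            "per_class": {
                "B/LB": {"precision": 0.97, "recall": 1.00,
                         "specificity": 0.97, "f1": 0.99, "support": 36},
                "P/LP": {"precision": 1.00, "recall": 0.97,
                         "specificity": 1.00, "f1": 0.99, "support": 38},
            },
            "weighted": {"precision": 0.99, "recall": 0.99, "f1": 0.99},
        },
    ]


def predictions_from_confusion(confusion: np.ndarray,
                               class_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Expand a confusion matrix into (truth, prediction) label arrays."""
    truth, pred = [], []
    for i, t_cls in enumerate(class_order):
        for j, p_cls in enumerate(class_order):
            truth.extend([t_cls] * int(confusion[i, j]))
            pred.extend([p_cls] * int(confusion[i, j]))
    return np.array(truth, dtype=object), np.array(pred, dtype=object)


# ---------------------------------------------------------------------------
# dataset simulation

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def simulate_dataset(cfg: SyntheticConfig, outdir: str | Path,
                     engine_cfg: EngineConfig | None = None
                     ) -> tuple[dict[str, Path], LabeledDataset]:
    """Generate the full offline input file set plus the labeled truth.

    Writes: variants.tsv (4-column list), annotations.csv, frequencies.csv,
    clinvar.tsv, repeats.bed and truth.csv.  Labels follow the evidence
    score bands, then flip with probability ``label_noise_rate`` to a
    uniformly drawn different class.  Byte-identical across runs with the
    same seed.
    """
    engine_cfg = engine_cfg or EngineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    alloc = _Allocator(rng)
    mixture = cfg.mixture()
    classes = ("P/LP", "VUS", "B/LB")

    realized: list[_Realized] = []
    vectors: list[CriterionVector] = []
    true_labels: list[str] = []
    scores: list[int] = []
    clinvar = ClinVarReference()
    repeats = IntervalSet()

    for _ in range(cfg.n_variants):
        cls = classes[rng.choice(3, p=mixture)]
        pattern = PATTERNS[cls][rng.integers(len(PATTERNS[cls]))]
        gene = ("BRCA1", "BRCA2")[rng.integers(2)]
        r = realize_pattern(pattern, gene, alloc, rng)
        for rec in r.clinvar_rows:
            clinvar.add(rec)
        if r.repeat_interval is not None:
            repeats.add(*r.repeat_interval)
        realized.append(r)

    for r in realized:
        vec = build_criterion_vector(r.variant, clinvar, engine_cfg)
        intended = CriterionVector(**{c: 1 for c in r.pattern})
        if vec != intended:
            raise AssertionError(
                f"generator/engine disagreement at {r.variant.key}: "
                f"intended {intended.to_dict()}, engine {vec.to_dict()}")
        vectors.append(vec)
        score = evidence_score(vec, cfg.evidence_weights)
        scores.append(score)
        true_labels.append(score_to_label(score, cfg))

    labels = list(true_labels)
    n_flipped = 0
    for i in range(len(labels)):
        if rng.random() < cfg.label_noise_rate:
            others = [c for c in classes if c != labels[i]]
            labels[i] = others[rng.integers(2)]
            n_flipped += 1
    if cfg.label_noise_rate > 0:
        log.info("label noise: flipped %d/%d labels", n_flipped, len(labels))

    paths = _write_files(outdir, realized, clinvar, repeats, labels, scores)
    keys = [r.variant.key for r in realized]
    dataset = LabeledDataset(keys=keys, vectors=vectors, labels=labels)
    return paths, dataset


def _write_files(outdir: Path, realized: list[_Realized],
                 clinvar: ClinVarReference, repeats: IntervalSet,
                 labels: list[str], scores: list[int]) -> dict[str, Path]:
    from .io_annotation import ANNOTATION_COLUMNS

    paths = {name: outdir / fname for name, fname in [
        ("variants", "variants.tsv"), ("annotations", "annotations.csv"),
        ("frequencies", "frequencies.csv"), ("clinvar", "clinvar.tsv"),
        ("repeats", "repeats.bed"), ("truth", "truth.csv")]}

    freq_fields = ("af_exac_nontcga", "af_gnomad_noncancer",
                   "ac_case", "an_case", "ac_control", "an_control")
    anno_fields = [c for c in ANNOTATION_COLUMNS
                   if c not in freq_fields and c != "in_repeat_region"
                   and not c.startswith("clinvar_")]

    with open(paths["variants"], "w") as fh:
        for r in realized:
            pos, ref, alt = r.raw_alleles
            fh.write(f"{r.variant.key.chrom}\t{pos}\t{ref}\t{alt}\n")

    with open(paths["annotations"], "w") as fh:
        fh.write(",".join(("chrom", "pos", "ref", "alt") + tuple(anno_fields)) + "\n")
        for r in realized:
            k = r.variant.key
            cells = [k.chrom, str(k.pos), k.ref or "-", k.alt or "-"]
            cells += [_fmt(getattr(r.variant, f)) for f in anno_fields]
            fh.write(",".join(cells) + "\n")

    with open(paths["frequencies"], "w") as fh:
        fh.write(",".join(("chrom", "pos", "ref", "alt") + freq_fields) + "\n")
        for r in realized:
            vals = [getattr(r.variant, f) for f in freq_fields]
            if all(v is None for v in vals):
                continue
            k = r.variant.key
            cells = [k.chrom, str(k.pos), k.ref or "-", k.alt or "-"]
            cells += [_fmt(v) for v in vals]
            fh.write(",".join(cells) + "\n")

    with open(paths["clinvar"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttranscript\tprotein_position\taa_ref"
                 "\taa_alt\tsignificance\treview_stars\tsingle_submitter"
                 "\tconflicting\n")
        for rec in sorted(clinvar.records, key=lambda r: r.key):
            key = rec.key
            fh.write("\t".join([
                key.chrom, str(key.pos), key.ref or "-", key.alt or "-",
                key.transcript, _fmt(rec.protein_position),
                rec.aa_ref or "", rec.aa_alt or "",
                rec.significance, "3", "false", "false"]) + "\n")

    repeats.to_bed(paths["repeats"])

    with open(paths["truth"], "w") as fh:
        fh.write("chrom,pos,ref,alt,label,latent_score\n")
        for r, label, score in zip(realized, labels, scores):
            k = r.variant.key
            fh.write(f"{k.chrom},{k.pos},{k.ref or '-'},{k.alt or '-'},"
                     f"{label},{score}\n")
    return paths
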