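"""Automated assignment of 17 ACMG-AMP evidence criteria to BRCA1/2 variants.

The engine codes each criterion as a binary flag from pre-computed
annotation.  Ten pathogenic-side criteria (PVS1, PS1, PS4, PM1, PM2, PM4,
PM5, PP2, PP3, PP5) and seven benign-side criteria (BA1, BS1, BP1, BP3,
BP4, BP6, BP7) are covered; PM1, PP2 and BP1 are constitutively 0 for
BRCA1/2 (well-studied functional domains are not free of benign missense
variants, and gene-level missense statistics are inconclusive), and the
remaining eleven ACMG-AMP criteria need per-case evidence (segregation,
de novo status, functional assays) that no annotation table carries.

Every numeric threshold lives in :class:`EngineConfig`, so a run can be
reproduced from its echoed configuration alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

import numpy as np
import yaml
from scipy.stats import hypergeom

from .io_annotation import (AnnotatedVariant, ClinVarReference, CRITERIA_ORDER)

log = logging.getLogger(__name__)

LOF_CONSEQUENCES = frozenset({
    "frameshift", "stop_gained", "stop_lost", "splice_acceptor", "splice_donor",
})


@dataclass(frozen=True)
class EngineConfig:
    """All numeric thresholds of the evidence rules, in one place.

    Defaults follow the published rule set for BRCA1/2: common variants
    above 5% AF are stand-alone benign (BA1), above 1% strong benign (BS1);
    case-control enrichment needs OR > 2 at p < 0.05 (PS4); in-silico
    deleteriousness needs GERP++_RS > 2 and splice scores > 0.6 (PP3/BP4/
    BP7); missense same-codon comparisons are gated on an MMSplice
    pathogenicity score < 0.85 so splice-mediated effects cannot masquerade
    as protein-level evidence.  The BRCA2 terminal-exon boundary (codon
    3326) marks the clinically tolerated truncation region exempt from
    PVS1.
    """

    ba1_af_threshold: float = 0.05
    bs1_af_threshold: float = 0.01
    ps4_or_threshold: float = 2.0
    ps4_p_threshold: float = 0.05
    gerp_threshold: float = 2.0
    splice_score_threshold: float = 0.6
    mmsplice_threshold: float = 0.85
    clinvar_min_stars: int = 2
    brca2_terminal_codon_boundary: int = 3326
    bp4_mode: str = "paper_complement"   # or "benign_concordance"
    lof_consequences: frozenset = field(default=LOF_CONSEQUENCES)

    def __post_init__(self) -> None:
        for name in ("ba1_af_threshold", "bs1_af_threshold", "ps4_or_threshold",
                     "ps4_p_threshold", "gerp_threshold", "splice_score_threshold",
                     "mmsplice_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bp4_mode not in ("paper_complement", "benign_concordance"):
            raise ValueError(f"unknown bp4_mode {self.bp4_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lof_consequences"] = sorted(self.lof_consequences)
        return d

    def header_lines(self) -> list[str]:
        return [f"# {k}={v}" for k, v in sorted(self.to_dict().items())]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "lof_consequences" in d:
            d["lof_consequences"] = frozenset(d["lof_consequences"])
        return cls(**d)


@dataclass(frozen=True)
class CriterionVector:
    """Ordered 17-bit evidence vector (canonical order = CRITERIA_ORDER)."""

    PVS1: int = 0
    PS1: int = 0
    PS4: int = 0
    PM1: int = 0
    PM2: int = 0
    PM4: int = 0
    PM5: int = 0
    PP2: int = 0
    PP3: int = 0
    PP5: int = 0
    BA1: int = 0
    BS1: int = 0
    BP1: int = 0
    BP3: int = 0
    BP4: int = 0
    BP6: int = 0
    BP7: int = 0

    def __post_init__(self) -> None:
        for name in CRITERIA_ORDER:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def to_list(self) -> list[int]:
        return [getattr(self, name) for name in CRITERIA_ORDER]

    def to_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in CRITERIA_ORDER}

    @classmethod
    def from_mapping(cls, m) -> "CriterionVector":
        return cls(**{k: int(v) for k, v in dict(m).items()})

    def check_invariants(self) -> None:
        """Mutual-exclusion and implication structure of the rule set."""
        v = self
        if v.PM1 or v.PP2 or v.BP1:
            raise AssertionError("PM1/PP2/BP1 must be constant 0")
        if v.PP3 and v.BP4:
            raise AssertionError("PP3 and BP4 are mutually exclusive")
        if v.PP5 and v.BP6:
            raise AssertionError("PP5 and BP6 are mutually exclusive")
        if v.PM4 and v.BP3:
            raise AssertionError("PM4 and BP3 are mutually exclusive")
        if v.PM2 and (v.BA1 or v.BS1):
            raise AssertionError("PM2 excludes BA1/BS1")
        if v.BA1 and not v.BS1:
            raise AssertionError("BA1 implies BS1")


# ---------------------------------------------------------------------------
# case-control statistics

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele-count table: rows = case/control, cols = alt/non-alt."""

    a: int  # case alt alleles
    b: int  # case non-alt alleles
    c: int  # control alt alleles
    d: int  # control non-alt alleles

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in contingency table")

    @classmethod
    def from_counts(cls, ac_case: int, an_case: int,
                    ac_control: int, an_control: int) -> "ContingencyTable2x2":
        return cls(ac_case, an_case - ac_case, ac_control, an_control - ac_control)


class OddsRatioResult(NamedTuple):
    value: float
    haldane_corrected: bool


def odds_ratio(t: ContingencyTable2x2) -> OddsRatioResult:
    """Sample odds ratio (a*d)/(b*c), Haldane-Anscombe corrected on zeros.

    With any zero cell, 0.5 is added to every cell so the ratio stays
    defined for the rare variants that dominate this problem; the result is
    flagged as corrected.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return OddsRatioResult((a * d) / (b * c), True)
    return OddsRatioResult((a * d) / (b * c), False)


_TIE_TOL = 1e-7  # relative tolerance when comparing point probabilities


def fisher_pvalues_for_margins(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p-values for every table with row margins (r1, r2)
    and first-column margin c1.

    Returns (support, p) where support holds the admissible values of cell
    ``a`` and p[i] is the sum of hypergeometric point probabilities over all
    tables at most as probable as the one with a = support[i] (point-
    probability two-sided convention, relative tie tolerance 1e-7).
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("degenerate table: zero row margin")
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(probs, kind="stable")
    cum = np.cumsum(probs[order])
    idx = np.searchsorted(probs[order], probs * (1.0 + _TIE_TOL), side="right")
    p = np.minimum(cum[np.maximum(idx, 1) - 1], 1.0)
    return support, p


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 allele-count table.

    A zero row margin (an empty cohort) is an error; a zero column margin
    leaves a single admissible table, hence p = 1.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    if r1 == 0 or r2 == 0:
        raise ValueError("degenerate table: zero row margin")
    c1 = t.a + t.c
    if c1 == 0 or t.b + t.d == 0:
        return 1.0
    support, p = fisher_pvalues_for_margins(r1, r2, c1)
    return float(p[t.a - support[0]])


# ---------------------------------------------------------------------------
# individual criteria

def assign_pvs1(v: AnnotatedVariant, cfg: EngineConfig) -> int:
    """Null variant in a gene where loss of function causes disease.

    All LoF consequences qualify, except truncations in the last amino
    acids of the last exon of BRCA2, which escape nonsense-mediated decay
    and are clinically tolerated.
    """
    if v.consequence not in cfg.lof_consequences:
        return 0
    if v.key.gene == "BRCA2":
        if v.exon_index is None or v.exon_total is None or v.protein_position is None:
            if v.consequence in ("frameshift", "stop_gained"):
                log.warning("%s: exon/codon fields absent; BRCA2 terminal-exon "
                            "exception not evaluable", v.key)
            return 1
        if (v.exon_index == v.exon_total
                and v.protein_position > cfg.brca2_terminal_codon_boundary):
            return 0
    return 1


def _splice_gate_open(v: AnnotatedVariant, cfg: EngineConfig) -> bool:
    # PS1/PM5 only stand if the nucleotide change is not predicted to act
    # through splicing; an absent MMSplice score is treated as permissive.
    if v.mmsplice_pathogenicity is None:
        log.debug("%s: MMSplice score absent; PS1/PM5 splice gate left open", v.key)
        return True
    return v.mmsplice_pathogenicity < cfg.mmsplice_threshold


def assign_ps1_pm5(v: AnnotatedVariant, clinvar: ClinVarReference,
                   cfg: EngineConfig) -> tuple[int, int]:
    """Same-codon comparisons against established pathogenic missense.

    PS1: an admissible pathogenic record makes the same amino-acid change
    via a different nucleotide change.  PM5: an admissible pathogenic
    missense exists at the same codon with a different substitution.  Both
    require the query to be missense and not splice-confounded.
    """
    if v.consequence != "missense" or v.protein_position is None or v.aa_alt is None:
        return 0, 0
    records = clinvar.pathogenic_missense_at(v.key.transcript, v.protein_position)
    if not records or not _splice_gate_open(v, cfg):
        return 0, 0
    ps1 = any(r.aa_alt == v.aa_alt and r.key != v.key for r in records)
    pm5 = (not ps1) and any(r.aa_alt != v.aa_alt for r in records)
    return int(ps1), int(pm5)


def assign_ps4(v: AnnotatedVariant, cfg: EngineConfig) -> int:
    """Case-control enrichment: OR above threshold at significant p."""
    counts = (v.ac_case, v.an_case, v.ac_control, v.an_control)
    if any(x is None for x in counts):
        log.debug("%s: case/control counts absent; PS4 = 0", v.key)
        return 0
    t = ContingencyTable2x2.from_counts(*counts)
    if t.a + t.b == 0 or t.c + t.d == 0:
        log.warning("%s: empty cohort; PS4 = 0", v.key)
        return 0
    orr = odds_ratio(t)
    if orr.value <= cfg.ps4_or_threshold:
        return 0
    p = fisher_exact_two_sided(t)
    return int(p < cfg.ps4_p_threshold)


def assign_frequency_criteria(v: AnnotatedVariant,
                              cfg: EngineConfig) -> tuple[int, int, int]:
    """(BA1, BS1, PM2) from pooled population allele frequencies.

    The working AF is the maximum over the sources that report one.  PM2
    fires only when the variant is absent (or zero) in both extracts —
    absence is informative for a dominant gene.
    """
    present = [x for x in (v.af_exac_nontcga, v.af_gnomad_noncancer) if x is not None]
    af = max(present) if present else None
    ba1 = int(af is not None and af > cfg.ba1_af_threshold)
    bs1 = int(af is not None and af > cfg.bs1_af_threshold)
    pm2 = int(all(x is None or x == 0.0
                  for x in (v.af_exac_nontcga, v.af_gnomad_noncancer)))
    return ba1, bs1, pm2


def assign_pm4_bp3(v: AnnotatedVariant) -> tuple[int, int]:
    """Protein-length changes: in-frame indels split on repeat context;
    stop-loss always extends the protein (PM4 regardless of repeats)."""
    inframe = v.consequence in ("inframe_insertion", "inframe_deletion")
    pm4 = int((inframe and not v.in_repeat_region) or v.consequence == "stop_lost")
    bp3 = int(inframe and v.in_repeat_region)
    return pm4, bp3


def _insilico_votes(v: AnnotatedVariant, cfg: EngineConfig) -> list[bool]:
    """Deleterious-vote per present in-silico score (absent = no vote)."""
    votes = []
    if v.metasvm_pred is not None:
        votes.append(v.metasvm_pred == "deleterious")
    if v.condel_pred is not None:
        votes.append(v.condel_pred == "deleterious")
    if v.gerp_rs is not None:
        votes.append(v.gerp_rs > cfg.gerp_threshold)
    if v.ada_score is not None:
        votes.append(v.ada_score > cfg.splice_score_threshold)
    if v.rf_score is not None:
        votes.append(v.rf_score > cfg.splice_score_threshold)
    return votes


def assign_pp3_bp4(v: AnnotatedVariant, cfg: EngineConfig) -> tuple[int, int]:
    """Computational evidence: PP3 when every present score is deleterious.

    In the default ``paper_complement`` mode BP4 is the complement of PP3
    whenever at least one score exists; ``benign_concordance`` instead
    requires every present score to be benign for BP4.
    """
    votes = _insilico_votes(v, cfg)
    if not votes:
        return 0, 0
    pp3 = int(all(votes))
    if cfg.bp4_mode == "paper_complement":
        bp4 = 1 - pp3
    else:
        bp4 = int(not any(votes))
    return pp3, bp4


def assign_bp7(v: AnnotatedVariant, cfg: EngineConfig) -> int:
    """Synonymous variant with no predicted splice impact at a position that
    is not conserved.

    Missing splice scores count as "no splice impact" (dbscSNV only covers
    splice-region positions); a missing conservation score blocks the call.
    """
    if v.consequence != "synonymous":
        return 0
    if v.gerp_rs is None or v.gerp_rs >= cfg.gerp_threshold:
        return 0
    for score in (v.ada_score, v.rf_score):
        if score is not None and score >= cfg.splice_score_threshold:
            return 0
    return 1


def assign_pp5_bp6(v: AnnotatedVariant,
                   clinvar: ClinVarReference) -> tuple[int, int]:
    """Reputable-source interpretation: exact-key ClinVar lookup on the
    admission-filtered reference."""
    sig = clinvar.significance_of(v.key)
    if sig in ("P", "LP"):
        return 1, 0
    if sig in ("B", "LB"):
        return 0, 1
    return 0, 0


def build_criterion_vector(v: AnnotatedVariant,
                           clinvar: Optional[ClinVarReference] = None,
                           cfg: Optional[EngineConfig] = None) -> CriterionVector:
    """Run every rule and assemble the ordered 17-bit vector.

    PM1, PP2 and BP1 are hard-wired to 0 for BRCA1/2.  Passing no ClinVar
    reference leaves PS1/PM5/PP5/BP6 at 0.
    """
    cfg = cfg or EngineConfig()
    clinvar = clinvar if clinvar is not None else ClinVarReference.empty()
    pvs1 = assign_pvs1(v, cfg)
    ps1, pm5 = assign_ps1_pm5(v, clinvar, cfg)
    ps4 = assign_ps4(v, cfg)
    ba1, bs1, pm2 = assign_frequency_criteria(v, cfg)
    pm4, bp3 = assign_pm4_bp3(v)
    pp3, bp4 = assign_pp3_bp4(v, cfg)
    bp7 = assign_bp7(v, cfg)
    pp5, bp6 = assign_pp5_bp6(v, clinvar)
    vec = CriterionVector(
        PVS1=pvs1, PS1=ps1, PS4=ps4, PM1=0, PM2=pm2, PM4=pm4, PM5=pm5,
        PP2=0, PP3=pp3, PP5=pp5, BA1=ba1, BS1=bs1, BP1=0, BP3=bp3,
        BP4=bp4, BP6=bp6, BP7=bp7,
    )
    vec.check_invariants()
    return vec


def assign_criteria(variants, clinvar=None, cfg=None) -> list[CriterionVector]:
    """Vectorize :func:`build_criterion_vector` over a variant list."""
    cfg = cfg or EngineConfig()
    vectors = [build_criterion_vector(v, clinvar, cfg) for v in variants]
    counts = {name: sum(getattr(vec, name) for vec in vectors)
              for name in CRITERIA_ORDER}
    log.info("criterion assignment counts over %d variants: %s", len(vectors), counts)
    return vectors
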