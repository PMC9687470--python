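"""Parsing, validation and merging of variant annotation tables.

BRCA1/BRCA2 variant interpretation starts from a plain variant list and a
set of pre-computed annotation extracts (VEP-style consequence table,
population allele frequencies, a ClinVar extract, repeat-region intervals).
This module turns those files into :class:`AnnotatedVariant` records, the
single in-memory container every evidence criterion consumes.

Coordinate conventions: variant keys are 1-based (VCF); interval arithmetic
is 0-based half-open (BED); conversion happens only at the boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

GENE_BY_CHROM = {"17": "BRCA1", "13": "BRCA2"}
TRANSCRIPT_BY_GENE = {"BRCA1": "NM_007294", "BRCA2": "NM_000059"}

CONSEQUENCES = frozenset({
    "missense", "synonymous", "stop_gained", "stop_lost", "frameshift",
    "inframe_insertion", "inframe_deletion", "splice_acceptor",
    "splice_donor", "other",
})

SIGNIFICANCES = frozenset({"P", "LP", "B", "LB", "VUS"})

_ALLELE_ALPHABET = frozenset("ACGT")


class ParseError(ValueError):
    """Fatal parsing problem (malformed line, missing mandatory column)."""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared prefix/suffix so allele pairs have a minimal canonical form.

    The "-" indel dialect is mapped to an empty allele first.  Left
    alignment proper would need reference sequence context; prefix/suffix
    trimming already makes key equality well-defined for same-site
    comparisons, which is what the evidence rules require.
    """
    ref = "" if ref == "-" else ref
    alt = "" if alt == "-" else alt
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of one variant (1-based, GRCh37)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in GENE_BY_CHROM:
            raise ValueError(f"chromosome {self.chrom!r} is not 13 or 17")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALLELE_ALPHABET:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} is not over ACGT")

    @property
    def gene(self) -> str:
        return GENE_BY_CHROM[self.chrom]

    @property
    def transcript(self) -> str:
        return TRANSCRIPT_BY_GENE[self.gene]

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos, ref, alt = normalize_alleles(int(pos), ref.upper(), alt.upper())
        return cls(_norm_chrom(str(chrom)), pos, ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref or '-'}>{self.alt or '-'}"


@dataclass
class AnnotatedVariant:
    """One variant with every annotation field the evidence criteria consume.

    ``None`` means "absent from the extract", which is distinct from zero
    (e.g. an allele frequency of 0.0 is an observation; ``None`` is not).
    """

    key: VariantKey
    consequence: str = "other"
    cds_position: Optional[int] = None
    protein_position: Optional[int] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    given_ref: Optional[str] = None
    exon_index: Optional[int] = None
    exon_total: Optional[int] = None
    af_exac_nontcga: Optional[float] = None
    af_gnomad_noncancer: Optional[float] = None
    ac_case: Optional[int] = None
    an_case: Optional[int] = None
    ac_control: Optional[int] = None
    an_control: Optional[int] = None
    metasvm_pred: Optional[str] = None       # "deleterious" | "tolerated"
    condel_pred: Optional[str] = None        # "deleterious" | "neutral"
    gerp_rs: Optional[float] = None
    ada_score: Optional[float] = None
    rf_score: Optional[float] = None
    mmsplice_pathogenicity: Optional[float] = None
    clinvar_significance: Optional[str] = None
    clinvar_review_stars: Optional[int] = None
    clinvar_single_submitter: bool = False
    clinvar_conflicting: bool = False
    in_repeat_region: bool = False

    def validate(self) -> None:
        v = self
        if v.consequence not in CONSEQUENCES:
            raise ValueError(f"{v.key}: unknown consequence {v.consequence!r}")
        for name in ("af_exac_nontcga", "af_gnomad_noncancer", "ada_score",
                     "rf_score", "mmsplice_pathogenicity"):
            x = getattr(v, name)
            if x is not None and not (0.0 <= x <= 1.0):
                raise ValueError(f"{v.key}: {name}={x} outside [0,1]")
        for ac_name, an_name in (("ac_case", "an_case"), ("ac_control", "an_control")):
            ac, an = getattr(v, ac_name), getattr(v, an_name)
            if ac is not None and ac < 0:
                raise ValueError(f"{v.key}: {ac_name}={ac} negative")
            if ac is not None and an is not None and ac > an:
                raise ValueError(f"{v.key}: {ac_name}={ac} exceeds {an_name}={an}")
        if (v.aa_ref is not None or v.aa_alt is not None) and v.protein_position is None:
            raise ValueError(f"{v.key}: amino-acid change without protein_position")
        if v.metasvm_pred not in (None, "deleterious", "tolerated"):
            raise ValueError(f"{v.key}: bad metasvm_pred {v.metasvm_pred!r}")
        if v.condel_pred not in (None, "deleterious", "neutral"):
            raise ValueError(f"{v.key}: bad condel_pred {v.condel_pred!r}")
        if v.clinvar_significance not in SIGNIFICANCES | {None}:
            raise ValueError(f"{v.key}: bad significance {v.clinvar_significance!r}")


# ---------------------------------------------------------------------------
# variant lists

def parse_variant_list(path: str | Path, dialect: str = "tsv4") -> list[VariantKey]:
    """Read a variant list (VCF 4.x or 4-column TSV) into normalized keys.

    Keys are deduplicated after normalization, preserving input order.
    Records on chromosomes other than 13/17 are rejected with a warning.
    Multi-allelic VCF records are split into one key per ALT allele.
    """
    if dialect not in ("vcf", "tsv4"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    keys: list[VariantKey] = []
    seen: set[VariantKey] = set()
    rejected = 0

    def push(chrom, pos, ref, alt, where: str) -> None:
        nonlocal rejected
        chrom = _norm_chrom(str(chrom))
        if chrom not in GENE_BY_CHROM:
            rejected += 1
            log.warning("%s: chromosome %r not in {13,17}; record rejected", where, chrom)
            return
        key = VariantKey.make(chrom, pos, ref, alt)
        if key not in seen:
            seen.add(key)
            keys.append(key)

    if dialect == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    push(rec.chrom, rec.pos, rec.ref, alt, f"{path}:{rec.chrom}:{rec.pos}")
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
                chrom, pos, ref, alt = parts
                try:
                    pos_i = int(pos)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from exc
                try:
                    push(chrom, pos_i, ref, alt, f"{path}:{lineno}")
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if rejected:
        log.warning("%s: %d record(s) rejected (off-target chromosome)", path, rejected)
    return keys


# ---------------------------------------------------------------------------
# annotated table

_KEY_COLUMNS = ("chrom", "pos", "ref", "alt")
_MANDATORY_COLUMNS = _KEY_COLUMNS + ("consequence",)
_INT_FIELDS = {"cds_position", "protein_position", "exon_index", "exon_total",
               "ac_case", "an_case", "ac_control", "an_control",
               "clinvar_review_stars"}
_FLOAT_FIELDS = {"af_exac_nontcga", "af_gnomad_noncancer", "gerp_rs",
                 "ada_score", "rf_score", "mmsplice_pathogenicity"}
_BOOL_FIELDS = {"clinvar_single_submitter", "clinvar_conflicting", "in_repeat_region"}

ANNOTATION_COLUMNS: tuple[str, ...] = tuple(
    f.name for f in fields(AnnotatedVariant) if f.name != "key")


def _parse_bool(cell: str) -> bool:
    return str(cell).strip().lower() in ("1", "true", "yes", "t")


def parse_annotated_table(path: str | Path) -> list[AnnotatedVariant]:
    """Parse the annotated-variant CSV into records.

    Empty cells map to absent (``None``).  Rows with out-of-range scores are
    rejected individually (error logged naming the field); a missing
    mandatory column is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    known = set(_KEY_COLUMNS) | set(ANNOTATION_COLUMNS)
    for col in df.columns:
        if col not in known:
            log.warning("%s: ignoring unknown column %r", path, col)
    out: list[AnnotatedVariant] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), 2):
        row = row._asdict()
        try:
            key = VariantKey.make(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            kwargs: dict = {}
            for name in ANNOTATION_COLUMNS:
                cell = str(row.get(name, "")).strip()
                if cell == "":
                    continue
                if name in _INT_FIELDS:
                    kwargs[name] = int(float(cell))
                elif name in _FLOAT_FIELDS:
                    kwargs[name] = float(cell)
                elif name in _BOOL_FIELDS:
                    kwargs[name] = _parse_bool(cell)
                else:
                    kwargs[name] = cell
            rec = AnnotatedVariant(key=key, **kwargs)
            rec.validate()
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            log.error("%s: row %d rejected: %s", path, i, exc)
            continue
        out.append(rec)
    if n_rejected:
        log.warning("%s: %d row(s) rejected", path, n_rejected)
    return out


# ---------------------------------------------------------------------------
# ClinVar reference

@dataclass(frozen=True)
class ClinVarRecord:
    key: VariantKey
    protein_position: Optional[int]
    aa_ref: Optional[str]
    aa_alt: Optional[str]
    significance: str

    @property
    def is_missense(self) -> bool:
        return (self.protein_position is not None
                and self.aa_ref is not None and self.aa_alt is not None
                and self.aa_ref != self.aa_alt
                and len(self.aa_ref) == 1 and len(self.aa_alt) == 1)


@dataclass
class ClinVarReference:
    """Admission-filtered ClinVar extract with key and codon indexes.

    Only records with review status >= 2 stars, not single-submitter and not
    conflicting are admitted, so downstream rules can never see an
    inadmissible interpretation.
    """

    by_key: dict[VariantKey, str] = field(default_factory=dict)
    records: list[ClinVarRecord] = field(default_factory=list)
    _by_codon: dict[tuple[str, int], list[ClinVarRecord]] = field(default_factory=dict)
    n_admitted: int = 0
    n_rejected: int = 0

    def add(self, rec: ClinVarRecord) -> None:
        self.by_key[rec.key] = rec.significance
        self.records.append(rec)
        if rec.protein_position is not None:
            self._by_codon.setdefault(
                (rec.key.transcript, rec.protein_position), []).append(rec)
        self.n_admitted += 1

    def significance_of(self, key: VariantKey) -> Optional[str]:
        return self.by_key.get(key)

    def records_at_codon(self, transcript: str, protein_position: int) -> list[ClinVarRecord]:
        return self._by_codon.get((transcript, protein_position), [])

    def pathogenic_missense_at(self, transcript: str,
                               protein_position: int) -> list[ClinVarRecord]:
        return [r for r in self.records_at_codon(transcript, protein_position)
                if r.is_missense and r.significance in ("P", "LP")]

    @classmethod
    def empty(cls) -> "ClinVarReference":
        return cls()


_CLINVAR_COLUMNS = ("chrom", "pos", "ref", "alt", "transcript", "protein_position",
                    "aa_ref", "aa_alt", "significance", "review_stars",
                    "single_submitter", "conflicting")


def load_clinvar_reference(path: str | Path, min_stars: int = 2) -> ClinVarReference:
    """Load the tab-delimited ClinVar extract, applying the admission filter."""
    path = Path(path)
    ref = ClinVarReference()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _CLINVAR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for i, row in enumerate(df.itertuples(index=False), 2):
        row = row._asdict()
        sig = row["significance"].strip()
        if sig not in SIGNIFICANCES:
            ref.n_rejected += 1
            log.warning("%s: row %d: unknown significance %r; rejected", path, i, sig)
            continue
        stars = int(float(row["review_stars"]))
        if (stars < min_stars or _parse_bool(row["single_submitter"])
                or _parse_bool(row["conflicting"])):
            ref.n_rejected += 1
            continue
        try:
            key = VariantKey.make(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        except ValueError as exc:
            ref.n_rejected += 1
            log.warning("%s: row %d rejected: %s", path, i, exc)
            continue
        pp = row["protein_position"].strip()
        ref.add(ClinVarRecord(
            key=key,
            protein_position=int(float(pp)) if pp else None,
            aa_ref=row["aa_ref"].strip() or None,
            aa_alt=row["aa_alt"].strip() or None,
            significance=sig,
        ))
    log.info("%s: %d ClinVar record(s) admitted, %d rejected",
             path, ref.n_admitted, ref.n_rejected)
    return ref


# ---------------------------------------------------------------------------
# repeat intervals

class IntervalSet:
    """Per-chromosome intervals, 0-based half-open (BED convention)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start},{end})")
        self._trees.setdefault(_norm_chrom(chrom), IntervalTree()).addi(start, end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(_norm_chrom(chrom))
        return bool(tree.overlap(start, end)) if tree is not None else False

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        ivs = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: BED3 needs 3 fields")
                ivs.add(parts[0], int(parts[1]), int(parts[2]))
        return ivs

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals():
                fh.write(f"{chrom}\t{start}\t{end}\n")


def variant_span(key: VariantKey) -> tuple[int, int]:
    """0-based half-open reference span affected by a variant.

    A pure insertion (empty ref after normalization) is given the single
    base at its insertion point, so insertions inside repeats still count
    as overlapping.
    """
    start = key.pos - 1
    return start, start + max(len(key.ref), 1)


def mark_repeat_overlap(variants: Sequence[AnnotatedVariant],
                        repeats: IntervalSet) -> list[AnnotatedVariant]:
    """Set ``in_repeat_region`` from interval overlap with the repeat track."""
    out = []
    for v in variants:
        start, end = variant_span(v.key)
        out.append(replace(v, in_repeat_region=repeats.overlaps(v.key.chrom, start, end)))
    return out


# ---------------------------------------------------------------------------
# frequency table + merging

_FREQ_COLUMNS = ("af_exac_nontcga", "af_gnomad_noncancer",
                 "ac_case", "an_case", "ac_control", "an_control")


def load_frequency_table(path: str | Path) -> dict[VariantKey, dict]:
    """Load the per-source population-frequency/count table (CSV).

    Columns: chrom,pos,ref,alt plus any of the frequency/count fields;
    empty cells are absent.  Conflicting duplicate rows for one key are
    fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    table: dict[VariantKey, dict] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        key = VariantKey.make(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        vals: dict = {}
        for name in _FREQ_COLUMNS:
            cell = str(row.get(name, "")).strip()
            if cell == "":
                continue
            vals[name] = float(cell) if name.startswith("af_") else int(float(cell))
        if key in table:
            if table[key] != vals:
                raise ParseError(f"{path}: conflicting duplicate rows for {key}")
            continue
        table[key] = vals
    return table


def merge_sources(variants: Sequence[AnnotatedVariant],
                  freq_table: Optional[Mapping[VariantKey, Mapping]] = None,
                  clinvar: Optional[ClinVarReference] = None,
                  repeats: Optional[IntervalSet] = None) -> list[AnnotatedVariant]:
    """Left-join frequency, ClinVar and repeat annotation onto the variants.

    Unmatched lookups leave fields absent; join statistics are logged.
    """
    out: list[AnnotatedVariant] = []
    n_freq = n_clinvar = 0
    for v in variants:
        if freq_table is not None:
            row = freq_table.get(v.key)
            if row is not None:
                n_freq += 1
                v = replace(v, **dict(row))
        if clinvar is not None:
            sig = clinvar.significance_of(v.key)
            if sig is not None:
                n_clinvar += 1
                v = replace(v, clinvar_significance=sig)
        out.append(v)
    if repeats is not None:
        out = mark_repeat_overlap(out, repeats)
    log.info("merge: %d/%d variants matched frequency table, %d matched ClinVar",
             n_freq, len(out), n_clinvar)
    return out


# ---------------------------------------------------------------------------
# criteria table output

#: canonical criterion column order used in every table and feature matrix
CRITERIA_ORDER: tuple[str, ...] = (
    "PVS1", "PS1", "PS4", "PM1", "PM2", "PM4", "PM5", "PP2", "PP3", "PP5",
    "BA1", "BS1", "BP1", "BP3", "BP4", "BP6", "BP7",
)

CLASS_LABELS = ("P/LP", "VUS", "B/LB")


@dataclass
class LabeledDataset:
    """Rows of (variant key, 17-bit criterion vector, class label)."""

    keys: list[VariantKey]
    vectors: list  # list[CriterionVector]
    labels: list[str]

    def __post_init__(self) -> None:
        if len({k for k in self.keys}) != len(self.keys):
            raise ValueError("duplicate variant keys in labeled dataset")
        bad = [l for l in self.labels if l not in CLASS_LABELS]
        if bad:
            raise ValueError(f"unknown class label(s) {sorted(set(bad))}")
        counts = {c: self.labels.count(c) for c in CLASS_LABELS}
        log.info("labeled dataset: %s", counts)

    def __len__(self) -> int:
        return len(self.keys)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASS_LABELS}

    def feature_matrix(self):
        import numpy as np

        return np.array([vec.to_list() for vec in self.vectors], dtype=int)


def write_criteria_table(rows: Iterable[tuple], path: str | Path,
                         config=None) -> None:
    """Write (key, vector[, label]) rows as CSV in the canonical column order.

    When an engine configuration is given its effective values are echoed as
    ``#`` comment lines in the file header.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    with_label = len(rows[0]) >= 3
    with open(path, "w", newline="") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        w = csv.writer(fh)
        header = list(_KEY_COLUMNS) + list(CRITERIA_ORDER)
        if with_label:
            header.append("label")
        w.writerow(header)
        for row in rows:
            key, vec = row[0], row[1]
            cells = [key.chrom, key.pos, key.ref or "-", key.alt or "-"]
            cells += vec.to_list()
            if with_label:
                cells.append(row[2])
            w.writerow(cells)


def read_criteria_table(path: str | Path):
    """Read back a criteria CSV; returns (keys, vectors, labels-or-None)."""
    from .engine import CriterionVector

    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    keys, vectors, labels = [], [], []
    has_label = "label" in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict()
        keys.append(VariantKey.make(row["chrom"], int(row["pos"]), row["ref"], row["alt"]))
        vectors.append(CriterionVector.from_mapping(
            {c: int(row[c]) for c in CRITERIA_ORDER}))
        if has_label:
            labels.append(row["label"])
    return keys, vectors, (labels if has_label else None)
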