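"""Sequence/table IO, affinity normalization, binder labeling and split construction.

The unit of all training and evaluation is a :class:`BindingRecord`:
one (allele, peptide) pair with a normalized binding affinity in [0, 1]
(log50k scale), an optional binary reactivity label and an optional
cross-validation fold id.

Affinities measured as IC50 in nM are mapped to [0, 1] with the log50k
transform ``1 - log(IC50) / log(50000)``; 500 nM lands on the
conventional binder threshold 0.426 and scores strictly above it are
labeled binders.

Coordinates are 0-based half-open internally; files written for users
carry 1-based inclusive positions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    InvalidAffinity,
    InvalidScore,
    InvalidSequence,
    UnknownAllele,
)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: IC50 (nM) anchor of the log50k scale; 50000 nM maps to score 0.
LOG50K_BASE = 50000.0

#: Normalized-affinity cutoff above which a pair is called a binder
#: (equals the log50k image of 500 nM, to 3 d.p.).
BINDER_THRESHOLD = 0.426

PSEUDO_SEQUENCE_LENGTH = 34


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MHCAllele:
    """An MHC class II molecule named by allele, represented by its
    pseudo-sequence (the 34 polymorphic groove-lining positions)."""

    name: str
    pseudo_sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.pseudo_sequence, what=f"allele {self.name}")

    def __len__(self) -> int:
        return len(self.pseudo_sequence)


@dataclass(frozen=True)
class Peptide:
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, what="peptide")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BindingRecord:
    """One observation: allele x peptide with affinity and/or label.

    ``affinity_norm`` is on the [0, 1] log50k scale; ``label`` is 1 for
    binder, 0 for nonbinder; ``fold`` is an integer CV fold id.  At
    least one of affinity/label must be present.
    """

    allele_name: str
    peptide: str
    affinity_norm: float | None = None
    label: int | None = None
    fold: int | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.peptide, what="peptide")
        if self.affinity_norm is None and self.label is None:
            raise InvalidAffinity(
                f"record ({self.allele_name}, {self.peptide}): neither "
                "affinity nor label present"
            )
        if self.affinity_norm is not None:
            a = float(self.affinity_norm)
            if not (0.0 <= a <= 1.0) or not math.isfinite(a):
                raise InvalidScore(f"affinity_norm {a!r} outside [0, 1]")
            self.affinity_norm = a
        if self.label is not None and self.label not in (0, 1):
            raise InvalidScore(f"label must be 0/1, got {self.label!r}")

    def effective_label(self, threshold: float = BINDER_THRESHOLD) -> int:
        """Explicit label if present, else derived from the affinity."""
        if self.label is not None:
            return int(self.label)
        return label_from_affinity(self.affinity_norm, threshold)


@dataclass
class Dataset:
    """Allele table plus binding records; every record's allele resolves."""

    alleles: dict[str, MHCAllele]
    records: list[BindingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.allele_name not in self.alleles:
                raise UnknownAllele(rec.allele_name)

    def __len__(self) -> int:
        return len(self.records)

    def allele_of(self, record: BindingRecord) -> MHCAllele:
        return self.alleles[record.allele_name]

    def subset(self, records: Iterable[BindingRecord]) -> "Dataset":
        return Dataset(alleles=self.alleles, records=list(records))


@dataclass(frozen=True)
class CoreAnnotation:
    """Experimentally annotated binding core of a pMHC complex."""

    complex_id: str
    peptide: str
    core_start: int  # 0-based
    core_length: int = 9

    def __post_init__(self) -> None:
        validate_sequence(self.peptide, what=f"complex {self.complex_id}")
        if self.core_start < 0 or self.core_start + self.core_length > len(self.peptide):
            raise InvalidScore(
                f"core [{self.core_start}, {self.core_start + self.core_length}) "
                f"outside peptide of length {len(self.peptide)}"
            )


# ---------------------------------------------------------------------------
# validation and transforms


def validate_sequence(seq: str, what: str = "sequence") -> str:
    if not isinstance(seq, str) or len(seq) < 1:
        raise InvalidSequence(f"{what}: empty or non-string sequence")
    bad = set(seq) - _CANONICAL_SET
    if bad:
        raise InvalidSequence(
            f"{what}: non-canonical residue(s) {''.join(sorted(bad))!r} in {seq!r}"
        )
    return seq


def log50k_transform(affinity_nM: float) -> float:
    """Map an IC50 (nM) to the [0, 1] log50k scale.

    ``1 - log(a)/log(50000)``, clamped to [0, 1] so affinities below
    1 nM or above 50000 nM stay on the scale. Strictly decreasing on
    (1, 50000) nM.
    """
    a = float(affinity_nM)
    if not math.isfinite(a) or a <= 0.0:
        raise InvalidAffinity(f"affinity must be positive and finite, got {affinity_nM!r}")
    score = 1.0 - math.log(a) / math.log(LOG50K_BASE)
    return min(1.0, max(0.0, score))


def inverse_log50k(score: float) -> float:
    """Inverse of the (unclamped) log50k transform: score -> IC50 nM."""
    s = float(score)
    if not math.isfinite(s) or not (0.0 <= s <= 1.0):
        raise InvalidScore(f"score must be in [0, 1], got {score!r}")
    return LOG50K_BASE ** (1.0 - s)


def label_from_affinity(score: float, threshold: float = BINDER_THRESHOLD) -> int:
    """1 (binder) iff score is strictly above the threshold."""
    s = float(score)
    if not math.isfinite(s) or not (0.0 <= s <= 1.0):
        raise InvalidScore(f"score must be in [0, 1], got {score!r}")
    return int(s > threshold)


# ---------------------------------------------------------------------------
# allele / core-annotation tables


def read_allele_table(path: str | Path) -> dict[str, MHCAllele]:
    """Read alleles from 2-column TSV (name, pseudo-sequence) or FASTA."""
    path = Path(path)
    text = path.read_text()
    alleles: dict[str, MHCAllele] = {}
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            alleles[rec.id] = MHCAllele(rec.id, str(rec.seq).upper())
        return alleles
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise InvalidSequence(f"{path}:{lineno}: expected 'name<TAB>pseudo-sequence'")
        alleles[parts[0]] = MHCAllele(parts[0], parts[1].upper())
    return alleles


def write_allele_table(alleles: Mapping[str, MHCAllele], path: str | Path) -> None:
    lines = [f"{name}\t{alleles[name].pseudo_sequence}" for name in sorted(alleles)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_core_table(path: str | Path) -> list[CoreAnnotation]:
    """Core annotations: TSV (complex_id, peptide, core_start_1based)."""
    out: list[CoreAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("complex"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise InvalidSequence(f"{path}:{lineno}: expected 3 columns")
        out.append(CoreAnnotation(parts[0], parts[1], int(parts[2]) - 1))
    return out


def write_core_table(annotations: Sequence[CoreAnnotation], path: str | Path) -> None:
    lines = ["complex_id\tpeptide\tcore_start"]
    for ann in annotations:
        lines.append(f"{ann.complex_id}\t{ann.peptide}\t{ann.core_start + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# binding tables


@dataclass
class TableIssue:
    lineno: int
    message: str


def read_binding_table(
    path: str | Path,
    alleles: Mapping[str, MHCAllele],
    dialect: str = "bd2016",
    threshold: float = BINDER_THRESHOLD,
    collect_errors: bool = False,
):
    """Read binding records from a whitespace/TSV table.

    The ``bd2016`` dialect is the NetMHCIIpan-style layout: whitespace
    separated ``peptide  affinity  allele  [fold]`` rows without a
    header. The ``generic_tsv`` dialect expects a header naming any of
    ``peptide, allele, affinity_nm, affinity_norm, label, fold``.

    Affinity values are auto-detected per file: if any value exceeds
    1.0 the column is taken as IC50 nM and passed through
    :func:`log50k_transform`; otherwise it is already normalized.
    Labels absent from the file are derived from the affinity.

    Returns the :class:`Dataset`, or ``(Dataset, issues)`` when
    ``collect_errors`` is true (malformed rows are then reported with
    line numbers instead of raising).
    """
    path = Path(path)
    if dialect not in ("bd2016", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    rows: list[tuple[int, dict]] = []
    lines = path.read_text().splitlines()

    if dialect == "generic_tsv":
        header_idx = next(
            (i for i, l in enumerate(lines) if l.strip() and not l.startswith("#")), None
        )
        if header_idx is None:
            raise InvalidSequence(f"{path}: empty table")
        cols = [c.strip().lower() for c in lines[header_idx].split("\t")]
        for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
            if not line.strip() or line.startswith("#"):
                continue
            vals = dict(zip(cols, (v.strip() for v in line.split("\t"))))
            rows.append((lineno, vals))
    else:
        for lineno, line in enumerate(lines, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                rows.append((lineno, {"_malformed": f"expected >= 3 columns, got {len(parts)}"}))
                continue
            vals = {"peptide": parts[0], "affinity": parts[1], "allele": parts[2]}
            if len(parts) > 3:
                vals["fold"] = parts[3]
            rows.append((lineno, vals))

    # auto-detect the affinity unit over the whole file
    raw_affinities = []
    for _, vals in rows:
        a = vals.get("affinity") or vals.get("affinity_nm") or vals.get("affinity_norm")
        try:
            raw_affinities.append(float(a))
        except (TypeError, ValueError):
            pass
    is_nM = any(a > 1.0 for a in raw_affinities)

    issues: list[TableIssue] = []
    records: list[BindingRecord] = []
    for lineno, vals in rows:
        try:
            if "_malformed" in vals:
                raise InvalidSequence(vals["_malformed"])
            allele = vals.get("allele")
            if allele not in alleles:
                raise UnknownAllele(f"allele {allele!r} not in allele table")
            affinity = None
            raw = vals.get("affinity") or vals.get("affinity_nm") or vals.get("affinity_norm")
            if raw not in (None, "", "NA"):
                a = float(raw)
                if "affinity_norm" in vals and "affinity" not in vals and "affinity_nm" not in vals:
                    affinity = a
                else:
                    affinity = log50k_transform(a) if is_nM else a
            label = None
            if vals.get("label") not in (None, "", "NA"):
                label = int(vals["label"])
            elif affinity is not None:
                label = label_from_affinity(affinity, threshold)
            fold = int(vals["fold"]) if vals.get("fold") not in (None, "", "NA") else None
            records.append(
                BindingRecord(
                    allele_name=allele,
                    peptide=vals["peptide"].upper(),
                    affinity_norm=affinity,
                    label=label,
                    fold=fold,
                )
            )
        except Exception as exc:  # noqa: BLE001 - collected with line number
            if collect_errors:
                issues.append(TableIssue(lineno, f"{type(exc).__name__}: {exc}"))
            else:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc

    dataset = Dataset(alleles=dict(alleles), records=records)
    if collect_errors:
        return dataset, issues
    return dataset


def write_binding_table(dataset: Dataset, path: str | Path) -> None:
    """Write records as TSV with a fixed column order (round-trips
    through :func:`read_binding_table` with dialect ``generic_tsv``)."""
    lines = ["peptide\tallele\taffinity_norm\tlabel\tfold"]
    for rec in dataset.records:
        aff = "NA" if rec.affinity_norm is None else f"{rec.affinity_norm:.6f}"
        lab = "NA" if rec.label is None else str(rec.label)
        fold = "NA" if rec.fold is None else str(rec.fold)
        lines.append(f"{rec.peptide}\t{rec.allele_name}\t{aff}\t{lab}\t{fold}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# splits


def split_lomo(dataset: Dataset, held_out_allele: str) -> tuple[Dataset, Dataset]:
    """Leave-one-molecule-out partition: test = all records of the
    held-out allele, train = everything else."""
    if held_out_allele not in dataset.alleles:
        raise UnknownAllele(held_out_allele)
    test = [r for r in dataset.records if r.allele_name == held_out_allele]
    if not test:
        raise UnknownAllele(f"allele {held_out_allele!r} has no records")
    train = [r for r in dataset.records if r.allele_name != held_out_allele]
    return dataset.subset(train), dataset.subset(test)


def filter_lomo_alleles(
    dataset: Dataset, min_obs: int = 40, min_binders: int = 3
) -> list[str]:
    """Alleles eligible as LOMO test molecules: observation count
    strictly greater than ``min_obs`` and at least ``min_binders``
    binding peptides; sorted for determinism."""
    obs: dict[str, int] = {}
    binders: dict[str, int] = {}
    for rec in dataset.records:
        obs[rec.allele_name] = obs.get(rec.allele_name, 0) + 1
        binders[rec.allele_name] = binders.get(rec.allele_name, 0) + rec.effective_label()
    return sorted(
        a for a in obs if obs[a] > min_obs and binders.get(a, 0) >= min_binders
    )


def split_folds(dataset: Dataset) -> dict[int, Dataset]:
    """Partition records by their fold id (records must carry folds)."""
    from .errors import MissingFolds

    by_fold: dict[int, list[BindingRecord]] = {}
    for rec in dataset.records:
        if rec.fold is None:
            raise MissingFolds("record without fold id")
        by_fold.setdefault(rec.fold, []).append(rec)
    return {f: dataset.subset(rs) for f, rs in sorted(by_fold.items())}


__all__ = [
    "CANONICAL_AA",
    "BINDER_THRESHOLD",
    "LOG50K_BASE",
    "PSEUDO_SEQUENCE_LENGTH",
    "MHCAllele",
    "Peptide",
    "BindingRecord",
    "Dataset",
    "CoreAnnotation",
    "TableIssue",
    "validate_sequence",
    "log50k_transform",
    "inverse_log50k",
    "label_from_affinity",
    "read_allele_table",
    "write_allele_table",
    "read_core_table",
    "write_core_table",
    "read_binding_table",
    "write_binding_table",
    "split_lomo",
    "filter_lomo_alleles",
    "split_folds",
]
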