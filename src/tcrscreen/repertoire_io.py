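"""Reading and writing clonotype tables, cohort manifests and feature matrices.

A clonotype is identified by the triple (CDR3 amino-acid sequence, V gene,
J gene).  Two table dialects are supported: the AIRR rearrangement standard
(``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``, ``productive``)
and an immunoSEQ-export-like layout (``aminoAcid``, ``vGeneName``,
``jGeneName``, ``count``).  Rows are validated, optionally filtered to
productive rearrangements, and aggregated under a canonical ``CDR3_V_J`` key.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("tcrscreen")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

Phenotype = Literal["case", "control", "unknown"]
PHENOTYPES = ("case", "control", "unknown")

#: column maps per dialect: logical name -> file column
DIALECTS: dict[str, dict[str, str]] = {
    "airr": {
        "cdr3_aa": "junction_aa",
        "v_gene": "v_call",
        "j_gene": "j_call",
        "count": "duplicate_count",
        "productive": "productive",
    },
    "immunoseq": {
        "cdr3_aa": "aminoAcid",
        "v_gene": "vGeneName",
        "j_gene": "jGeneName",
        "count": "count",
    },
}

_GENE_RE = re.compile(r"^(?P<family>TR[AB][VDJ]\d+)(?P<gene>-\d+)?(?:\*\d+)?$")


class RepertoireError(ValueError):
    """Raised for malformed clonotype tables or empty repertoires."""


class ConfigurationError(ValueError):
    """Raised when required columns or options cannot be resolved."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One rearrangement: CDR3 amino acids, V gene, J gene, template count."""

    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    productive: bool = True

    def validate(self) -> None:
        if not self.cdr3_aa:
            raise RepertoireError("empty CDR3 sequence")
        if not set(self.cdr3_aa) <= AMINO_ACIDS:
            raise RepertoireError(f"invalid CDR3 alphabet: {self.cdr3_aa!r}")
        if self.count < 1:
            raise RepertoireError(f"count must be >= 1, got {self.count}")


def _strip_allele(label: str) -> str:
    return label.split("*", 1)[0]


def collapse_v_family(label: str) -> str:
    """Collapse a V gene label to its family (``TRBV12-3*01`` -> ``TRBV12``)."""
    m = _GENE_RE.match(label)
    if m is None:
        logger.warning("unparseable V gene label %r used verbatim", label)
        return label
    return m.group("family")


def normalize_j_gene(label: str) -> str:
    """Strip the allele from a J gene label (``TRBJ1-1*01`` -> ``TRBJ1-1``)."""
    m = _GENE_RE.match(label)
    if m is None:
        logger.warning("unparseable J gene label %r used verbatim", label)
        return label
    return _strip_allele(label)


def clonotype_key(
    record: ClonotypeRecord, v_resolution: Literal["family", "gene"] = "family"
) -> str:
    """Canonical ``CDR3_V_J`` identity string for a clonotype.

    With ``v_resolution="family"`` the V label is collapsed to its family
    (allele and ``-n`` gene suffix stripped); with ``"gene"`` only the allele
    is stripped.  The J label always keeps its ``-n`` suffix, allele stripped.
    Unparseable gene labels pass through verbatim (with a warning).
    """
    if v_resolution == "family":
        v = collapse_v_family(record.v_gene)
    elif v_resolution == "gene":
        v = _strip_allele(record.v_gene)
    else:
        raise ConfigurationError(f"unknown v_resolution {v_resolution!r}")
    j = normalize_j_gene(record.j_gene)
    return f"{record.cdr3_aa}_{v}_{j}"


@dataclass
class Repertoire:
    """One sample's deduplicated clonotype table plus its phenotype label.

    ``records`` is keyed by canonical clonotype key; duplicate input rows are
    merged by summing counts at construction time.
    """

    sample_id: str
    phenotype: Phenotype
    records: dict[str, ClonotypeRecord]
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if not self.records:
            raise RepertoireError(f"sample {self.sample_id!r}: empty repertoire")

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        phenotype: Phenotype,
        records: Iterable[ClonotypeRecord],
        v_resolution: Literal["family", "gene"] = "family",
        load_report: dict | None = None,
    ) -> "Repertoire":
        merged: dict[str, ClonotypeRecord] = {}
        for rec in records:
            rec.validate()
            key = clonotype_key(rec, v_resolution)
            v = collapse_v_family(rec.v_gene) if v_resolution == "family" else _strip_allele(rec.v_gene)
            j = normalize_j_gene(rec.j_gene)
            prev = merged.get(key)
            count = rec.count + (prev.count if prev is not None else 0)
            merged[key] = ClonotypeRecord(rec.cdr3_aa, v, j, count, rec.productive)
        return cls(sample_id, phenotype, merged, load_report or {})

    def keys(self) -> set[str]:
        return set(self.records)

    @property
    def richness(self) -> int:
        """Number of unique clonotypes ("productive uniques")."""
        return len(self.records)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records.values())

    def counts(self) -> list[int]:
        return [r.count for r in self.records.values()]


def _is_productive(cdr3: str, flag: object) -> bool:
    if isinstance(flag, str):
        if flag.strip().upper() in ("T", "TRUE", "1", "YES"):
            flag = True
        elif flag.strip().upper() in ("F", "FALSE", "0", "NO"):
            flag = False
    if flag is False:
        return False
    # stop codon "*" or frame-shift marker in the junction means non-productive
    return "*" not in cdr3 and "_" not in cdr3 and bool(cdr3)


def read_clonotype_table(
    path: str | Path,
    dialect: Literal["immunoseq", "airr"] = "airr",
    column_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    phenotype: Phenotype = "unknown",
    productive_only: bool = True,
    v_resolution: Literal["family", "gene"] = "family",
) -> Repertoire:
    """Load one sample's clonotype table into a canonicalized :class:`Repertoire`.

    Rows failing validation (empty/invalid CDR3, non-positive count, or
    non-productive when ``productive_only``) are dropped and tallied in the
    returned repertoire's ``load_report``.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    cols = dict(DIALECTS[dialect])
    if column_map:
        cols.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical in ("cdr3_aa", "v_gene", "j_gene", "count"):
        if cols[logical] not in df.columns:
            raise ConfigurationError(
                f"{path.name}: required column {cols[logical]!r} ({logical}) missing"
            )

    report = {
        "rows_read": len(df),
        "dropped_nonproductive": 0,
        "dropped_invalid_cdr3": 0,
        "dropped_bad_count": 0,
    }
    records: list[ClonotypeRecord] = []
    prod_col = cols.get("productive")
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        cdr3 = str(row[cols["cdr3_aa"]]).strip() if pd.notna(row[cols["cdr3_aa"]]) else ""
        flag = row.get(prod_col) if prod_col in df.columns else None
        productive = _is_productive(cdr3, flag)
        if productive_only and not productive:
            report["dropped_nonproductive"] += 1
            continue
        if not cdr3 or not set(cdr3) <= AMINO_ACIDS:
            report["dropped_invalid_cdr3"] += 1
            continue
        try:
            count = int(float(row[cols["count"]]))
        except (TypeError, ValueError):
            report["dropped_bad_count"] += 1
            continue
        if count < 1:
            report["dropped_bad_count"] += 1
            continue
        records.append(
            ClonotypeRecord(
                cdr3.upper(),
                str(row[cols["v_gene"]]).strip(),
                str(row[cols["j_gene"]]).strip(),
                count,
                productive,
            )
        )
    report["rows_kept"] = len(records)
    if not records:
        raise RepertoireError(f"{path}: no valid rows after filtering")
    return Repertoire.from_records(
        sample_id or path.stem, phenotype, records, v_resolution, load_report=report
    )


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: str
    phenotype: Phenotype
    split: Literal["train", "test"]


@dataclass
class CohortManifest:
    """Sample-to-file assignment with phenotype and train/test split."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate sample_ids in manifest")
        train_ph = {e.phenotype for e in self.entries if e.split == "train"}
        if not {"case", "control"} <= train_ph:
            raise ConfigurationError("train split must contain both phenotypes")

    def split_entries(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "path", "phenotype", "split"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"manifest missing columns: {missing}")
    entries = [
        ManifestEntry(r.sample_id, r.path, r.phenotype, r.split)
        for r in df.itertuples(index=False)
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame([e.__dict__ for e in manifest.entries]).to_csv(
        path, sep="\t", index=False
    )


def load_cohort(
    manifest: CohortManifest,
    base_dir: str | Path = ".",
    dialect: Literal["immunoseq", "airr"] = "airr",
    **read_kwargs,
) -> dict[str, list[Repertoire]]:
    """Load every manifest entry, returning ``{"train": [...], "test": [...]}``."""
    base = Path(base_dir)
    out: dict[str, list[Repertoire]] = {"train": [], "test": []}
    for e in manifest.entries:
        p = Path(e.path)
        if not p.is_absolute():
            p = base / p
        rep = read_clonotype_table(
            p, dialect=dialect, sample_id=e.sample_id, phenotype=e.phenotype, **read_kwargs
        )
        out[e.split].append(rep)
    return out


def write_matrix(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV: first column ``sample_id``, then features.

    Integer-valued matrices (e.g. 0/1 presence data) are written with integer
    tokens so the file round-trips byte-identically.
    """
    from .features import FeatureMatrix  # deferred: features imports this module

    assert isinstance(matrix, FeatureMatrix)
    df = matrix.to_frame()
    df.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix(path: str | Path):
    from .features import FeatureMatrix

    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return FeatureMatrix.from_frame(df)


def write_load_report(repertoires: Sequence[Repertoire], path: str | Path) -> None:
    payload = {r.sample_id: r.load_report for r in repertoires}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
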