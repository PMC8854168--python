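"""Reading, validating and class-assigning de novo mutation (DNM) tables.

A DNM record is one de novo variant call in one proband, annotated with a
gene symbol, a consequence term and (for missense calls) an in-silico
deleteriousness score in [0, 1].  Records are binned into the four variant
classes used throughout the pipeline:

* ``LoF`` — loss of function: stopgain, stoploss, canonical splicing and
  frameshift calls;
* ``Dmis`` / ``Tmis`` — missense predicted deleterious / tolerated, split at
  a configurable score threshold (default 0.7, compared with ``>=`` so the
  boundary goes to Dmis);
* ``synonymous`` — the normalisation class for all burden statistics;
* ``other`` — anything else (inframe indels, startloss ...), counted but
  excluded from burden tests.

The derived aggregate ``Pfun`` (putative functional) = LoF + Dmis is never
stored; it is always recomputed from its parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled consequence vocabulary for DNM tables.
CONSEQUENCES = (
    "stopgain",
    "stoploss",
    "splicing",
    "frameshift",
    "missense",
    "synonymous",
    "other",
)

#: Consequence terms classified as loss of function.
LOF_CONSEQUENCES = frozenset({"stopgain", "stoploss", "splicing", "frameshift"})

#: Variant classes, in canonical column order ("Pfun" is derived, not listed).
VARIANT_CLASSES = ("LoF", "Dmis", "Tmis", "synonymous", "other")

#: Classes entering burden tests (Pfun is their derived union of LoF+Dmis).
BURDEN_CLASSES = ("LoF", "Dmis", "Pfun", "Tmis")

DEFAULT_DMIS_THRESHOLD = 0.7

MANDATORY_COLUMNS = ("study_id", "disorder", "sample_id", "gene", "consequence")


class ClassificationError(ValueError):
    """A record cannot be assigned to a variant class."""


class DNMTableError(ValueError):
    """A DNM table is structurally unusable (e.g. missing a mandatory column)."""


@dataclass(frozen=True)
class DNMRecord:
    """One de novo variant call in one proband."""

    study_id: str
    disorder: str
    sample_id: str
    gene: str
    consequence: str
    score: float | None = None
    #: Unknown input columns, preserved verbatim for round-tripping.
    extra: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip())


@dataclass
class ReadResult:
    """Valid records plus a row-level error report from one table read."""

    records: list[DNMRecord]
    #: (1-based data line number, message) for every rejected row.
    errors: list[tuple[int, str]]

    def raise_on_errors(self) -> "ReadResult":
        if self.errors:
            lines = "; ".join(f"line {n}: {msg}" for n, msg in self.errors)
            raise DNMTableError(f"{len(self.errors)} malformed row(s): {lines}")
        return self


def classify(record: DNMRecord, dmis_threshold: float = DEFAULT_DMIS_THRESHOLD) -> str:
    """Assign a variant class to one record.

    LoF consequences map to ``LoF``; missense splits into ``Dmis`` (score >=
    threshold) and ``Tmis``; ``synonymous`` and ``other`` map to themselves.
    A missense record without a score is an error, never a silent guess.
    """
    if not 0.0 <= dmis_threshold <= 1.0:
        raise ValueError(f"dmis_threshold must be in [0, 1], got {dmis_threshold}")
    cons = record.consequence
    if cons not in CONSEQUENCES:
        raise ClassificationError(
            f"unknown consequence {cons!r} for record {record.sample_id}/{record.gene}"
        )
    if cons in LOF_CONSEQUENCES:
        return "LoF"
    if cons == "missense":
        if record.score is None:
            raise ClassificationError(
                f"missense record {record.sample_id}/{record.gene} has no score"
            )
        return "Dmis" if record.score >= dmis_threshold else "Tmis"
    return cons  # synonymous, other


#: Package-root alias; the bare name would shadow this submodule there.
classify_record = classify


def _parse_row(row: Mapping[str, object], extra_cols: Sequence[str]) -> DNMRecord:
    cons = str(row["consequence"]).strip()
    if cons not in CONSEQUENCES:
        raise ValueError(f"consequence {cons!r} not in vocabulary")
    raw_score = row.get("score")
    score: float | None = None
    if raw_score is not None and str(raw_score) != "" and not pd.isna(raw_score):
        score = float(raw_score)
        if cons != "missense":
            logger.warning(
                "score %s on non-missense row (%s/%s) ignored",
                score, row["sample_id"], row["gene"],
            )
            score = None
        elif not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
    return DNMRecord(
        study_id=str(row["study_id"]),
        disorder=str(row["disorder"]),
        sample_id=str(row["sample_id"]),
        gene=str(row["gene"]),
        consequence=cons,
        score=score,
        extra={c: str(row[c]) for c in extra_cols},
    )


def read_dnm_table(path: str | Path) -> ReadResult:
    """Read a tab-separated DNM table.

    Missing mandatory columns raise :class:`DNMTableError`; malformed rows
    (bad consequence term, score out of range) are collected into the
    returned error report with their data line numbers, never silently
    dropped.  Unknown columns are preserved on each record for round-trips.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DNMTableError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS and c != "score"]
    records: list[DNMRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            records.append(_parse_row(row, extra_cols))
        except ValueError as exc:
            errors.append((i, str(exc)))
    return ReadResult(records=records, errors=errors)


def _format_score(score: float | None) -> str:
    if score is None:
        return ""
    return format(score, "g")


def write_dnm_table(records: Iterable[DNMRecord], path: str | Path) -> None:
    """Write records as a tab-separated table (inverse of :func:`read_dnm_table`)."""
    records = list(records)
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    cols = list(MANDATORY_COLUMNS) + ["score"] + extra_cols
    rows = []
    for rec in records:
        row = {
            "study_id": rec.study_id,
            "disorder": rec.disorder,
            "sample_id": rec.sample_id,
            "gene": rec.gene,
            "consequence": rec.consequence,
            "score": _format_score(rec.score),
        }
        for c in extra_cols:
            row[c] = rec.extra.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass
class ClassCountMatrix:
    """Per-cohort DNM counts by variant class, plus trio totals.

    ``counts`` is indexed by cohort label with one column per class in
    :data:`VARIANT_CLASSES`; ``n_trios`` shares the index.  The derived
    Pfun column is exposed through :attr:`pfun` / :meth:`to_frame` and is
    always LoF + Dmis, never stored.
    """

    counts: pd.DataFrame
    n_trios: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(VARIANT_CLASSES), fill_value=0)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative DNM count")
        self.n_trios = self.n_trios.reindex(self.counts.index)
        if self.n_trios.isna().any() or (self.n_trios <= 0).any():
            raise ValueError("every cohort needs a positive trio count")
        self.n_trios = self.n_trios.astype(int)

    @property
    def cohorts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def pfun(self) -> pd.Series:
        return self.counts["LoF"] + self.counts["Dmis"]

    def class_count(self, cohort: str, variant_class: str) -> int:
        if variant_class == "Pfun":
            return int(self.pfun.loc[cohort])
        return int(self.counts.loc[cohort, variant_class])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with n_trios and the derived Pfun column."""
        out = self.counts.copy()
        out.insert(0, "n_trios", self.n_trios)
        out.insert(3, "Pfun", self.pfun)
        out.index.name = "cohort"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClassCountMatrix":
        counts = df[[c for c in VARIANT_CLASSES if c in df.columns]].copy()
        return cls(counts=counts, n_trios=df["n_trios"])


def count_matrix(
    records: Iterable[DNMRecord],
    trio_counts: Mapping[str, int],
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD,
) -> ClassCountMatrix:
    """Classify records and tally them into a per-cohort class-count matrix.

    Every cohort in ``trio_counts`` appears in the output even with zero
    records; a record whose disorder has no trio count is an error.
    """
    labels = list(trio_counts)
    tallies = pd.DataFrame(0, index=labels, columns=list(VARIANT_CLASSES), dtype=int)
    for rec in records:
        if rec.disorder not in trio_counts:
            raise DNMTableError(
                f"record disorder {rec.disorder!r} has no trio count; "
                f"known labels: {', '.join(labels)}"
            )
        tallies.loc[rec.disorder, classify(rec, dmis_threshold)] += 1
    return ClassCountMatrix(
        counts=tallies, n_trios=pd.Series(trio_counts, dtype=int)
    )


def gene_class_counts(
    records: Iterable[DNMRecord],
    dmis_threshold: float = DEFAULT_DMIS_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Per-cohort, per-gene, per-class DNM count tables.

    Returns a mapping cohort label -> DataFrame indexed by gene with one
    column per variant class.  Sample ids appearing in more than one cohort
    trigger a warning (possible double counting when cohorts are pooled).
    """
    records = list(records)
    seen: dict[str, str] = {}
    for rec in records:
        prev = seen.setdefault(rec.sample_id, rec.disorder)
        if prev != rec.disorder:
            logger.warning(
                "sample id %s appears in cohorts %s and %s; pooled counts may "
                "double-count", rec.sample_id, prev, rec.disorder,
            )
    out: dict[str, pd.DataFrame] = {}
    rows: dict[str, dict[tuple[str, str], int]] = {}
    for rec in records:
        cls = classify(rec, dmis_threshold)
        rows.setdefault(rec.disorder, {})
        key = (rec.gene, cls)
        rows[rec.disorder][key] = rows[rec.disorder].get(key, 0) + 1
    for cohort, tally in rows.items():
        ser = pd.Series(tally, dtype=int)
        df = ser.unstack(fill_value=0)
        df = df.reindex(columns=list(VARIANT_CLASSES), fill_value=0)
        df.index.name = "gene"
        out[cohort] = df
    return out
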