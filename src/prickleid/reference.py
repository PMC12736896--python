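"""Reference (training) collections of rose stem and leaf-rachis fragments.

A reference collection holds fragment-level prickle counts for plants of
known taxonomic identity: for each fragment the taxon, the organ it came
from, its length in cm, and how many prickles of each of the three
morphotypes (T1 short hooked wide-based, T2 thin slightly curved, TO
everything else) it bears.  These counts are the training data from which
per-taxon type likelihoods are estimated.

CSV interchange schema (comma-separated, UTF-8, "." decimal mark, header
mandatory)::

    taxon,organ,length_cm,n_T1,n_T2,n_TO,source_id

Observations of individual archaeological prickles use a second schema::

    id,length_mm,base_width_mm,curvature,assigned_type

with empty cells meaning "absent".
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PrickleType",
    "Curvature",
    "Organ",
    "FragmentRecord",
    "ReferenceCollection",
    "PrickleObservation",
    "TaxonSummary",
    "normalize_taxon",
    "read_reference_csv",
    "write_reference_csv",
    "read_observations_csv",
    "summarize_by_taxon",
]

_WS = re.compile(r"\s+")


def normalize_taxon(name: str) -> str:
    """Collapse internal whitespace and strip a taxon label.

    Comparison of taxon labels is whitespace-normalized but case-sensitive:
    ``"R.  moschata Herrm."`` equals ``"R. moschata Herrm."`` while
    ``"r. moschata herrm."`` does not.
    """
    out = _WS.sub(" ", name).strip()
    if not out:
        raise ValidationError("taxon label must be non-empty")
    return out


class PrickleType(str, enum.Enum):
    """The three prickle morphotypes; TO is the catch-all."""

    T1 = "T1"
    T2 = "T2"
    TO = "TO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed iteration order used everywhere counts or probabilities are laid out.
TYPES = (PrickleType.T1, PrickleType.T2, PrickleType.TO)


class Curvature(str, enum.Enum):
    HOOKED = "hooked"
    SLIGHTLY_CURVED = "slightly_curved"
    STRAIGHT = "straight"
    UNKNOWN = "unknown"


class Organ(str, enum.Enum):
    STEM = "stem"
    LEAF_RACHIS = "leaf_rachis"


@dataclass(frozen=True)
class FragmentRecord:
    """One measured stem or leaf-rachis fragment of a known-taxon plant."""

    taxon: str
    organ: Organ
    length_cm: float
    counts: Mapping[PrickleType, int]
    source_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "taxon", normalize_taxon(self.taxon))
        object.__setattr__(self, "organ", Organ(self.organ))
        if not (self.length_cm > 0) or not math.isfinite(self.length_cm):
            raise ValidationError(
                f"fragment length must be positive, got {self.length_cm}"
            )
        counts = {PrickleType(t): int(n) for t, n in dict(self.counts).items()}
        if set(counts) != set(TYPES):
            raise ValidationError(
                f"counts must cover exactly T1/T2/TO, got {sorted(c.value for c in counts)}"
            )
        if any(n < 0 for n in counts.values()):
            raise ValidationError(f"negative prickle count in {counts}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReferenceCollection:
    """An ordered set of fragment records with their taxon roster.

    ``taxa`` lists taxa in first-appearance order; every record's taxon is
    on the roster and the roster has no duplicates.
    """

    records: list[FragmentRecord] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.taxa:
            self.taxa = _first_appearance([r.taxon for r in self.records])
        self.validate()

    def validate(self) -> None:
        seen = set()
        for t in self.taxa:
            if t in seen:
                raise ValidationError(f"duplicate taxon in roster: {t!r}")
            seen.add(t)
        for i, r in enumerate(self.records):
            if r.taxon not in seen:
                raise ValidationError(
                    f"record {i} taxon {r.taxon!r} not on the taxon roster"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceCollection):
            return NotImplemented
        return self.taxa == other.taxa and self.records == other.records

    def subset(self, organ_filter: str = "both") -> "ReferenceCollection":
        """Records restricted to one organ (taxon roster preserved)."""
        if organ_filter == "both":
            recs = list(self.records)
        else:
            organ = Organ(organ_filter)
            recs = [r for r in self.records if r.organ is organ]
        return ReferenceCollection(records=recs, taxa=list(self.taxa))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon": r.taxon,
                "organ": r.organ.value,
                "length_cm": r.length_cm,
                "n_T1": r.counts[PrickleType.T1],
                "n_T2": r.counts[PrickleType.T2],
                "n_TO": r.counts[PrickleType.TO],
                "source_id": r.source_id,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=REFERENCE_COLUMNS)


@dataclass(frozen=True)
class PrickleObservation:
    """One archaeological prickle.

    Either measured dimensions plus a curvature class, or a pre-assigned
    morphotype, must be present; both may be.
    """

    id: str
    length_mm: float | None = None
    base_width_mm: float | None = None
    curvature: Curvature = Curvature.UNKNOWN
    assigned_type: PrickleType | None = None

    def __post_init__(self):
        object.__setattr__(self, "curvature", Curvature(self.curvature))
        if self.assigned_type is not None:
            object.__setattr__(self, "assigned_type", PrickleType(self.assigned_type))
        for dim in ("length_mm", "base_width_mm"):
            v = getattr(self, dim)
            if v is not None and not v > 0:
                raise ValidationError(f"{dim} must be positive, got {v}")
        has_measurements = (
            self.length_mm is not None and self.base_width_mm is not None
        )
        if self.assigned_type is None and not has_measurements:
            raise ValidationError(
                f"observation {self.id!r} needs either an assigned type or "
                "both dimensions"
            )


REFERENCE_COLUMNS = [
    "taxon",
    "organ",
    "length_cm",
    "n_T1",
    "n_T2",
    "n_TO",
    "source_id",
]

OBSERVATION_COLUMNS = ["id", "length_mm", "base_width_mm", "curvature", "assigned_type"]


def _first_appearance(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return list(seen)


def read_reference_csv(path) -> ReferenceCollection:
    """Read a reference collection from CSV (schema in the module docstring).

    Row order is preserved and the taxon roster is built in first-appearance
    order.  A missing column raises :class:`SchemaError` naming the column;
    a bad value raises :class:`ValidationError` naming the 1-based data row.
    """
    df = pd.read_csv(path, dtype={"taxon": str, "organ": str, "source_id": str})
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"reference CSV {path} is missing column(s): {', '.join(missing)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                FragmentRecord(
                    taxon=row.taxon,
                    organ=row.organ,
                    length_cm=float(row.length_cm),
                    counts={
                        PrickleType.T1: int(row.n_T1),
                        PrickleType.T2: int(row.n_T2),
                        PrickleType.TO: int(row.n_TO),
                    },
                    source_id="" if pd.isna(row.source_id) else str(row.source_id),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return ReferenceCollection(records=records)


def write_reference_csv(coll: ReferenceCollection, path) -> Path:
    """Write a collection to CSV; write∘read∘write is byte-stable."""
    path = Path(path)
    coll.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def read_observations_csv(path) -> list[PrickleObservation]:
    """Read archaeological prickle observations (empty cell = absent)."""
    df = pd.read_csv(path, dtype={"id": str, "curvature": str, "assigned_type": str})
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"observations CSV {path} is missing column(s): {', '.join(missing)}"
        )
    obs = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            obs.append(
                PrickleObservation(
                    id=str(row.id),
                    length_mm=None if pd.isna(row.length_mm) else float(row.length_mm),
                    base_width_mm=None
                    if pd.isna(row.base_width_mm)
                    else float(row.base_width_mm),
                    curvature=Curvature.UNKNOWN
                    if pd.isna(row.curvature)
                    else Curvature(row.curvature),
                    assigned_type=None
                    if pd.isna(row.assigned_type)
                    else PrickleType(row.assigned_type),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return obs


@dataclass(frozen=True)
class TaxonSummary:
    """Per-taxon descriptive statistics of a reference collection."""

    taxon: str
    n_fragments: int
    mean: Mapping[PrickleType, float]
    sd: Mapping[PrickleType, float]
    total_length_cm: float
    density_per_cm: float
    empty: bool = False


def summarize_by_taxon(
    coll: ReferenceCollection, organ_filter: str = "both"
) -> dict[str, TaxonSummary]:
    """Mean and SD of per-fragment counts per type, plus prickles per cm.

    Means are arithmetic means over fragments; SD is the sample standard
    deviation (n-1 denominator, 0 for a single fragment); density is total
    prickles over total fragment length.  A taxon with no fragments under
    the organ filter gets an explicit ``empty=True`` summary rather than
    being silently dropped.
    """
    sub = coll.subset(organ_filter)
    by_taxon: dict[str, list[FragmentRecord]] = {t: [] for t in coll.taxa}
    for r in sub.records:
        by_taxon[r.taxon].append(r)

    out: dict[str, TaxonSummary] = {}
    for taxon, recs in by_taxon.items():
        if not recs:
            out[taxon] = TaxonSummary(
                taxon=taxon,
                n_fragments=0,
                mean={t: float("nan") for t in TYPES},
                sd={t: float("nan") for t in TYPES},
                total_length_cm=0.0,
                density_per_cm=float("nan"),
                empty=True,
            )
            continue
        n = len(recs)
        mean = {}
        sd = {}
        for t in TYPES:
            xs = [r.counts[t] for r in recs]
            m = sum(xs) / n
            mean[t] = m
            sd[t] = (
                math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1)) if n > 1 else 0.0
            )
        total_len = sum(r.length_cm for r in recs)
        total_prickles = sum(r.total for r in recs)
        out[taxon] = TaxonSummary(
            taxon=taxon,
            n_fragments=n,
            mean=mean,
            sd=sd,
            total_length_cm=total_len,
            density_per_cm=total_prickles / total_len,
        )
    return out
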