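"""Tabular inputs for the risk assessment: parasitism/mortality surveys and host records.

Two kinds of table feed the analysis.  *Mortality tables* hold one observed
parasitism (or mortality) proportion per sampled cohort, labelled with the
parasitoid agent, the elevation stratum and whether the value is an apparent
mortality (raw proportion parasitized in a field sample) or a marginal attack
rate (competing-risks-corrected generational mortality).  *Host-record lists*
hold the published host range of an agent — species, family and origin — and
support the taxonomic screening step of the risk assessment: would the
non-target species have been flagged from records available before the agent
was introduced?

The packaged study tables are available through :func:`builtin_dataset`.
Values are kept exactly as printed; non-detections in the apparent-mortality
table are coded 0.001 (a stand-in the source used, not a true zero) and can be
recoded to zero with ``treat_point001_as_zero=True`` where an analysis wants
real zeros.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MORTALITY_TYPES",
    "STRATA",
    "ORIGINS",
    "MortalityRecord",
    "HostRecord",
    "SurveyDataset",
    "OverlapReport",
    "load_mortality_table",
    "load_host_records",
    "write_mortality_table",
    "builtin_dataset",
    "taxonomic_overlap_flag",
]

MORTALITY_TYPES = frozenset({"apparent", "marginal"})
STRATA = frozenset({"low", "medium", "high", "unspecified"})
ORIGINS = frozenset({"endemic", "adventive", "introduced", "uncertain"})

#: Builtin fixture names -> (packaged file, kind)
_BUILTINS: dict[str, tuple[str, str]] = {
    "table4_apparent": ("table4_apparent.csv", "mortality"),
    "table5_marginal": ("table5_marginal.csv", "mortality"),
    "hosts_cmarginiventris_hawaii": ("hosts_cmarginiventris_hawaii.csv", "hosts"),
    "hosts_mlaphygmae_hawaii": ("hosts_mlaphygmae_hawaii.csv", "hosts"),
    "hosts_tflavoorbitalis_hawaii": ("hosts_tflavoorbitalis_hawaii.csv", "hosts"),
    "hosts_cmarginiventris_native": ("hosts_cmarginiventris_native.csv", "hosts"),
    "hosts_mlaphygmae_native": ("hosts_mlaphygmae_native.csv", "hosts"),
}


class FormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class ValidationError(ValueError):
    """A table row violates a value constraint (range, vocabulary)."""


@dataclass(frozen=True)
class MortalityRecord:
    """One observed mortality proportion for one agent in one sampled cohort."""

    agent_id: str
    datum_index: int
    rate: float
    mortality_type: str = "apparent"
    stratum: str = "unspecified"

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValidationError(f"rate {self.rate!r} outside [0, 1]")
        if self.datum_index < 1:
            raise ValidationError(f"datum_index must be positive, got {self.datum_index}")
        if self.mortality_type not in MORTALITY_TYPES:
            raise ValidationError(
                f"mortality_type {self.mortality_type!r} not in {sorted(MORTALITY_TYPES)}"
            )
        if self.stratum not in STRATA:
            raise ValidationError(f"stratum {self.stratum!r} not in {sorted(STRATA)}")


@dataclass(frozen=True)
class HostRecord:
    """One published host association: species, family, origin class."""

    species: str
    family: str
    origin: str = "uncertain"
    is_target: bool = False

    def __post_init__(self) -> None:
        if not self.family:
            raise ValidationError("family must be non-empty")
        if not self.species:
            raise ValidationError("species must be non-empty")
        if self.origin not in ORIGINS:
            raise ValidationError(f"origin {self.origin!r} not in {sorted(ORIGINS)}")

    @property
    def genus(self) -> str:
        """First whitespace-delimited token of the binomial."""
        return self.species.split()[0]


@dataclass
class SurveyDataset:
    """An ordered collection of mortality records plus free-form metadata."""

    records: list[MortalityRecord]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for rec in self.records:
            key = (rec.agent_id, rec.mortality_type, rec.datum_index)
            if key in seen:
                raise ValidationError(
                    f"duplicate datum_index {rec.datum_index} for agent "
                    f"{rec.agent_id!r} ({rec.mortality_type})"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def agents(self) -> list[str]:
        """Agent ids in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.agent_id not in out:
                out.append(rec.agent_id)
        return out

    def rates(self, agent_id: str | None = None) -> list[float]:
        """Rates in row order, optionally restricted to one agent."""
        return [r.rate for r in self.records if agent_id is None or r.agent_id == agent_id]

    def for_agent(self, agent_id: str) -> "SurveyDataset":
        recs = [r for r in self.records if r.agent_id == agent_id]
        if not recs:
            raise KeyError(f"no records for agent {agent_id!r}; have {self.agents}")
        return SurveyDataset(records=recs, metadata=dict(self.metadata))

    def recode_point001_as_zero(self) -> "SurveyDataset":
        """Return a copy with the 0.001 non-detection stand-in recoded to 0."""
        recs = [replace(r, rate=0.0) if r.rate == 0.001 else r for r in self.records]
        return SurveyDataset(records=recs, metadata=dict(self.metadata))


@dataclass(frozen=True)
class OverlapReport:
    """Result of screening a non-target taxon against a host list."""

    level: str  # "genus" | "family" | "none"
    matches: tuple[HostRecord, ...]

    def __bool__(self) -> bool:
        return self.level != "none"


def _parse_rate(raw: str, row_num: int) -> float:
    try:
        rate = float(raw)
    except ValueError:
        raise ValidationError(f"row {row_num}: rate {raw!r} is not numeric") from None
    if not (0.0 <= rate <= 1.0):
        raise ValidationError(f"row {row_num}: rate {rate} outside [0, 1]")
    return rate


def load_mortality_table(
    path: str | Path,
    mortality_type: str | None = None,
    *,
    treat_point001_as_zero: bool = False,
) -> SurveyDataset:
    """Read a mortality CSV (columns ``datum,agent,rate[,stratum,mortality_type]``).

    Parameters
    ----------
    path
        CSV file; comma-separated, UTF-8, ``.`` decimal, header mandatory.
    mortality_type
        Label applied to every row ("apparent" or "marginal").  If the file
        carries a ``mortality_type`` column it must agree; if neither is
        given, "apparent" is assumed.
    treat_point001_as_zero
        Recode the 0.001 non-detection stand-in to true zero.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("datum", "agent", "rate"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        records: list[MortalityRecord] = []
        for row_num, row in enumerate(reader, start=1):
            rate = _parse_rate(row["rate"], row_num)
            try:
                datum = int(row["datum"])
            except ValueError:
                raise ValidationError(
                    f"row {row_num}: datum {row['datum']!r} is not an integer"
                ) from None
            mt = row.get("mortality_type") or mortality_type or "apparent"
            if mortality_type is not None and mt != mortality_type:
                raise ValidationError(
                    f"row {row_num}: mortality_type {mt!r} conflicts with "
                    f"requested {mortality_type!r}"
                )
            records.append(
                MortalityRecord(
                    agent_id=row["agent"],
                    datum_index=datum,
                    rate=rate,
                    mortality_type=mt,
                    stratum=row.get("stratum") or "unspecified",
                )
            )
    ds = SurveyDataset(records=records, metadata={"source": str(path)})
    if treat_point001_as_zero:
        ds = ds.recode_point001_as_zero()
    return ds


def write_mortality_table(dataset: SurveyDataset, path: str | Path) -> Path:
    """Write a SurveyDataset back to the canonical CSV schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["datum", "agent", "rate", "stratum", "mortality_type"])
        for rec in dataset.records:
            writer.writerow(
                [rec.datum_index, rec.agent_id, repr(rec.rate), rec.stratum, rec.mortality_type]
            )
    return path


def load_host_records(path: str | Path) -> list[HostRecord]:
    """Read a host-record CSV (columns ``species,family,origin,is_target``)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("species", "family"):
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        out = []
        for row in reader:
            out.append(
                HostRecord(
                    species=row["species"],
                    family=row["family"],
                    origin=(row.get("origin") or "uncertain").lower(),
                    is_target=(row.get("is_target", "False").strip().lower() == "true"),
                )
            )
    return out


def builtin_dataset(name: str) -> SurveyDataset | list[HostRecord]:
    """Return a packaged study table, values identical to print.

    Mortality fixtures (``table4_apparent``, ``table5_marginal``) come back as
    :class:`SurveyDataset`; host fixtures as a list of :class:`HostRecord`.
    """
    try:
        fname, kind = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin dataset {name!r}; valid names: {sorted(_BUILTINS)}"
        ) from None
    ref = resources.files("biopra.data").joinpath(fname)
    with resources.as_file(ref) as path:
        if kind == "mortality":
            ds = load_mortality_table(path)
            ds.metadata["source"] = f"builtin:{name}"
            return ds
        return load_host_records(path)


def taxonomic_overlap_flag(
    native_hosts: Iterable[HostRecord],
    nontarget_family: str,
    nontarget_genus: str,
) -> OverlapReport:
    """Screen a non-target taxon against a published host list.

    Returns the highest taxonomic level at which the non-target overlaps any
    host on the list: ``genus`` (same genus recorded as a host — the strongest
    pre-introduction warning), ``family`` (only confamilial hosts recorded), or
    ``none``.  Matching is case-insensitive on the plain name strings.
    """
    hosts = list(native_hosts)
    if not hosts:
        raise ValueError("host collection is empty")
    fam = nontarget_family.strip().lower()
    gen = nontarget_genus.strip().lower()
    genus_hits = tuple(h for h in hosts if h.genus.lower() == gen)
    family_hits = tuple(h for h in hosts if h.family.lower() == fam)
    if genus_hits:
        return OverlapReport(level="genus", matches=genus_hits)
    if family_hits:
        return OverlapReport(level="family", matches=family_hits)
    return OverlapReport(level="none", matches=())
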