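"""Domain containers for FMT engraftment analysis.

Four tabular objects cover the whole pipeline:

* :class:`AbundanceTable` — species-level (mOTU-style) relative abundances,
  taxa x samples.
* :class:`CohortManifest` — who is a donor, who is a recipient, which donor
  each recipient received, disease subtype, treatment arm and visit day.
* :class:`SNVTable` — per-species, per-position biallelic variant calls with
  per-sample read coverage and alternative-allele frequency.
* :class:`ClinicalTable` — long-format clinical indexes per subject and visit.

Each container validates its invariants on construction and is otherwise a
thin wrapper around :class:`pandas.DataFrame`.  Positions are 0-based on the
species reference; visit time points are normalised to integer day offsets
(baseline = 0).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

COLUMN_SUM_TOL = 1e-6

ROLES = frozenset({"donor", "recipient"})
ARMS = frozenset({"allogenic", "autologous", "none"})
SUBTYPES = frozenset({"CD", "UC", "healthy", "metabolic"})

_TIMEPOINT_ALIASES = {"baseline": 0, "day3": 3, "day7": 7, "day30": 30}


def parse_timepoint(value) -> int:
    """Normalise a time point label to an integer day offset.

    Accepts ``"baseline"`` (0), ``"dayN"``, ``"dN"``, or anything int-like.
    """
    if isinstance(value, (int, np.integer)):
        day = int(value)
    else:
        text = str(value).strip().lower()
        if text in _TIMEPOINT_ALIASES:
            day = _TIMEPOINT_ALIASES[text]
        else:
            m = re.fullmatch(r"(?:day|d)?\s*(-?\d+)", text)
            if m is None:
                raise ValidationError(f"unrecognised timepoint {value!r}")
            day = int(m.group(1))
    if day < 0:
        raise ValidationError(f"timepoint day offset must be >= 0, got {day}")
    return day


def _check_unique(values: Iterable, what: str) -> None:
    values = pd.Index(values)
    if values.has_duplicates:
        dups = values[values.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class AbundanceTable:
    """Relative-abundance matrix, taxa as rows and samples as columns.

    Values are relative abundances in [0, 1]; each sample column must sum to
    at most ``1 + 1e-6``.  Columns are *not* renormalised here — callers
    decide.  Taxa that are zero in every sample are retained.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("AbundanceTable.data must be a DataFrame")
        _check_unique(df.index, "taxon ids")
        _check_unique(df.columns, "sample ids")
        values = df.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            raise ValidationError("abundance table contains non-finite values")
        if (values < 0).any():
            bad = df.columns[(values < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative abundance in sample(s) {bad[:5]}")
        sums = values.sum(axis=0)
        over = sums > 1.0 + COLUMN_SUM_TOL
        if over.any():
            bad = df.columns[over].tolist()
            raise ValidationError(
                f"column sum > 1 + {COLUMN_SUM_TOL:g} in sample(s) {bad[:5]}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, sample_id: str) -> pd.Series:
        """Abundance profile of one sample (taxa-indexed Series)."""
        from .errors import NotFoundError

        if sample_id not in self.data.columns:
            raise NotFoundError(f"sample {sample_id!r} not in abundance table")
        return self.data[sample_id]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, AbundanceTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class Pair:
    """One recipient and the donor whose material they received."""

    recipient: str
    donor: str
    subtype: str
    arm: str
    baseline_sample: str | None
    donor_sample: str | None
    post_samples: Mapping[int, str] = field(default_factory=dict)


@dataclass
class CohortManifest:
    """Sample-level manifest linking recipients, donors, arms and visits.

    ``records`` columns: sample_id, subject_id, role, donor_id, subtype,
    arm, day (integer offset; 0 = baseline).
    """

    records: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "role", "donor_id", "subtype", "arm", "day")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing column(s) {missing}")
        df = df.copy()
        df["day"] = [parse_timepoint(v) for v in df["day"]]
        df["donor_id"] = df["donor_id"].fillna("").astype(str)
        self.records = df.reset_index(drop=True)

        _check_unique(df["sample_id"], "sample ids")
        for col, allowed in (("role", ROLES), ("arm", ARMS), ("subtype", SUBTYPES)):
            bad = set(df[col]) - allowed
            if bad:
                raise ValidationError(f"invalid {col} value(s) {sorted(bad)}")

        donors = set(df.loc[df["role"] == "donor", "subject_id"])
        recip = df[df["role"] == "recipient"]
        allo = recip[recip["arm"] == "allogenic"]
        dangling = set(allo["donor_id"]) - donors
        if dangling:
            raise ValidationError(
                f"allogenic recipient(s) reference unknown donor(s) {sorted(dangling)}"
            )
        auto = recip[recip["arm"] == "autologous"]
        bad_auto = auto[auto["donor_id"] != auto["subject_id"]]
        if len(bad_auto):
            raise ValidationError(
                "autologous records must have donor_id equal to their own "
                f"subject_id: {bad_auto['subject_id'].tolist()[:5]}"
            )
        key = recip[["subject_id", "day"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (subject, timepoint) for recipients: {dup[:5]}")

    @property
    def donor_subjects(self) -> list[str]:
        df = self.records
        return sorted(set(df.loc[df["role"] == "donor", "subject_id"]))

    @property
    def recipient_subjects(self) -> list[str]:
        df = self.records
        return sorted(set(df.loc[df["role"] == "recipient", "subject_id"]))

    def donor_sample_of(self, donor_subject: str) -> str | None:
        df = self.records
        rows = df[(df["subject_id"] == donor_subject) & (df["role"] == "donor")]
        if rows.empty:
            return None
        return rows.iloc[0]["sample_id"]

    def sample_for(self, subject_id: str, day: int) -> str | None:
        df = self.records
        rows = df[
            (df["subject_id"] == subject_id)
            & (df["role"] == "recipient")
            & (df["day"] == day)
        ]
        if rows.empty:
            return None
        return rows.iloc[0]["sample_id"]

    def subtype_of(self, subject_id: str) -> str:
        df = self.records
        rows = df[df["subject_id"] == subject_id]
        if rows.empty:
            from .errors import NotFoundError

            raise NotFoundError(f"unknown subject {subject_id!r}")
        return rows.iloc[0]["subtype"]

    def pairs(self) -> list[Pair]:
        """One :class:`Pair` per recipient, with resolved sample ids."""
        df = self.records
        recip = df[df["role"] == "recipient"]
        out: list[Pair] = []
        for subject, grp in recip.groupby("subject_id", sort=True):
            first = grp.iloc[0]
            donor = first["donor_id"]
            baseline = self.sample_for(subject, 0)
            if first["arm"] == "autologous":
                donor_sample = baseline
            else:
                donor_sample = self.donor_sample_of(donor) if donor else None
            post = {
                int(row["day"]): row["sample_id"]
                for _, row in grp.iterrows()
                if int(row["day"]) > 0
            }
            out.append(
                Pair(
                    recipient=subject,
                    donor=donor,
                    subtype=first["subtype"],
                    arm=first["arm"],
                    baseline_sample=baseline,
                    donor_sample=donor_sample,
                    post_samples=dict(sorted(post.items())),
                )
            )
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortManifest) and self.records.equals(other.records)


@dataclass
class SNVTable:
    """Biallelic variant table: loci metadata plus per-sample matrices.

    ``loci`` is indexed by (species_id, position) with columns ref_allele and
    alt_allele; ``coverage`` and ``freq`` share that index with one column
    per sample.  ``freq`` is the alternative-allele frequency in [0, 1] and
    is NaN wherever coverage is 0 (frequency is undefined without reads).
    """

    loci: pd.DataFrame
    coverage: pd.DataFrame
    freq: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.loci.index
        if idx.nlevels != 2:
            raise ValidationError("loci must be indexed by (species_id, position)")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].tolist()
            raise ValidationError(f"duplicate (species, position): {dups[:5]}")
        positions = idx.get_level_values(1)
        if (np.asarray(positions) < 0).any():
            raise ValidationError("positions must be >= 0")
        if not (self.coverage.index.equals(idx) and self.freq.index.equals(idx)):
            raise ValidationError("coverage/freq index must match loci index")
        if not self.coverage.columns.equals(self.freq.columns):
            raise ValidationError("coverage and freq must have identical samples")
        cov = self.coverage.to_numpy()
        if (cov < 0).any():
            raise ValidationError("coverage must be >= 0")
        fr = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(fr, initial=0.0) < 0 or np.nanmax(fr, initial=0.0) > 1:
                raise ValidationError("alt_frequency must lie in [0, 1]")
        zero_cov = cov == 0
        has_freq = ~np.isnan(fr)
        bad = zero_cov & has_freq
        if bad.any():
            logger.warning(
                "coercing %d frequency value(s) at coverage 0 to missing", int(bad.sum())
            )
            fr = fr.copy()
            fr[bad] = np.nan
            self.freq = pd.DataFrame(fr, index=idx, columns=self.freq.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coverage.columns)

    @property
    def species_ids(self) -> list[str]:
        return sorted(set(self.loci.index.get_level_values(0)))

    def has_species(self, species_id: str) -> bool:
        return species_id in self.loci.index.get_level_values(0)

    def species_slice(self, species_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(coverage, freq) restricted to one species, indexed by position."""
        from .errors import NotFoundError

        if not self.has_species(species_id):
            raise NotFoundError(f"species {species_id!r} absent from SNV table")
        cov = self.coverage.xs(species_id, level=0)
        fr = self.freq.xs(species_id, level=0)
        return cov, fr

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SNVTable)
            and self.loci.equals(other.loci)
            and self.coverage.equals(other.coverage)
            and self.freq.equals(other.freq)
        )


@dataclass
class ClinicalTable:
    """Long-format clinical metadata: one value per (subject, day, index)."""

    records: pd.DataFrame

    REQUIRED = ("subject_id", "day", "index_name", "value")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing column(s) {missing}")
        df = df.copy()
        df["day"] = [parse_timepoint(v) for v in df["day"]]
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        key = df[["subject_id", "day", "index_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (subject, day, index): {dup[:5]}")
        self.records = df.reset_index(drop=True)

    @property
    def index_names(self) -> list[str]:
        return sorted(set(self.records["index_name"]))

    def wide(self, day: int) -> pd.DataFrame:
        """Subjects x indexes matrix at one visit day."""
        sub = self.records[self.records["day"] == day]
        return sub.pivot(index="subject_id", columns="index_name", values="value")

    def __eq__(self, other) -> bool:
        return isinstance(other, ClinicalTable) and self.records.equals(other.records)
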