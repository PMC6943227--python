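"""Strain-level engraftment via determinant SNV positions.

For each donor–recipient pair and species, the *determinant set* is built
from the two baseline samples alone: positions whose alternative allele is
confidently present in the donor and absent in the recipient are
donor-specific; the reverse are recipient-specific.  Tracking those
positions in post-FMT samples yields a donor and a recipient *retention
fraction* per time point, a displacement/coexistence classification, and a
newly-arising-SNV rate.  Identical donor and recipient baselines (the
autologous control) produce empty determinant sets by construction.

Presence calls are threshold-based: a position needs ``cov_min`` reads to
be resolved at all, is *present* when the allele frequency is at least
``present_min`` and *absent* when it is at most ``absent_max``.  The
defaults (5x, 0.20, 0.10) are set so that at typical 20x coverage one or
two miscalled reads (~1% per-read error) still count as absent — which
keeps the retention estimator essentially unbiased — while a genuine minor
strain carrying the allele in at least a fifth of the reads is called
present.  All three are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import UndefinedInputError, ValidationError

logger = logging.getLogger(__name__)

# presence-call state codes (vectorised path)
ABSENT, PRESENT, UNRESOLVED = 0, 1, 2

CLASSIFICATIONS = ("donor_takeover", "recipient_persistence", "coexistence", "indeterminate")


@dataclass(frozen=True)
class PresenceThresholds:
    cov_min: int = 5
    present_min: float = 0.20
    absent_max: float = 0.10

    def __post_init__(self) -> None:
        if self.cov_min < 1:
            raise ValidationError("cov_min must be >= 1")
        if not 0 <= self.absent_max < self.present_min <= 1:
            raise ValidationError(
                "need 0 <= absent_max < present_min <= 1, got "
                f"absent_max={self.absent_max}, present_min={self.present_min}"
            )


@dataclass(frozen=True)
class PresenceCall:
    state: str  # 'present' | 'absent' | 'unresolved'
    coverage: int
    alt_frequency: float | None


def call_presence(
    coverage: int,
    alt_frequency: float | None,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> PresenceCall:
    """Classify one position in one sample as present/absent/unresolved."""
    if coverage < 0:
        raise ValidationError("coverage must be >= 0")
    freq = None if alt_frequency is None or np.isnan(alt_frequency) else float(alt_frequency)
    if coverage < thresholds.cov_min or freq is None:
        state = "unresolved"
    elif freq >= thresholds.present_min:
        state = "present"
    elif freq <= thresholds.absent_max:
        state = "absent"
    else:
        state = "unresolved"
    return PresenceCall(state=state, coverage=int(coverage), alt_frequency=freq)


def call_presence_array(
    coverage: np.ndarray, freq: np.ndarray, thresholds: PresenceThresholds = PresenceThresholds()
) -> np.ndarray:
    """Vectorised presence calls; returns codes ABSENT/PRESENT/UNRESOLVED."""
    coverage = np.asarray(coverage)
    freq = np.asarray(freq, dtype=float)
    out = np.full(coverage.shape, UNRESOLVED, dtype=np.int8)
    resolved = (coverage >= thresholds.cov_min) & ~np.isnan(freq)
    out[resolved & (freq >= thresholds.present_min)] = PRESENT
    out[resolved & (freq <= thresholds.absent_max)] = ABSENT
    return out


@dataclass
class DeterminantSet:
    """Baseline-defined donor- and recipient-specific positions of a species."""

    pair_id: str
    species_id: str
    donor_specific: pd.Index
    recipient_specific: pd.Index
    n_total_assessed: int

    def __post_init__(self) -> None:
        if len(self.donor_specific.intersection(self.recipient_specific)):
            raise ValidationError("donor- and recipient-specific sets must be disjoint")

    @property
    def n_determinant(self) -> int:
        return len(self.donor_specific) + len(self.recipient_specific)


def build_determinant_set(
    snv,
    donor_sample: str,
    recipient_baseline_sample: str,
    species: str,
    thresholds: PresenceThresholds = PresenceThresholds(),
    min_positions: int = 20,
    pair_id: str = "",
) -> DeterminantSet | None:
    """Define determinant positions for one pair and species from baseline.

    Positions unresolved in either baseline sample are excluded.  Returns
    None (with a logged reason) when fewer than ``min_positions`` positions
    are informative — the species is simply not trackable for this pair.
    """
    cov, freq = snv.species_slice(species)
    for s in (donor_sample, recipient_baseline_sample):
        if s not in cov.columns:
            raise ValidationError(f"sample {s!r} absent from SNV table")
    d_state = call_presence_array(cov[donor_sample].to_numpy(), freq[donor_sample].to_numpy(), thresholds)
    r_state = call_presence_array(
        cov[recipient_baseline_sample].to_numpy(),
        freq[recipient_baseline_sample].to_numpy(),
        thresholds,
    )
    donor_specific = cov.index[(d_state == PRESENT) & (r_state == ABSENT)]
    recipient_specific = cov.index[(d_state == ABSENT) & (r_state == PRESENT)]
    n_informative = len(donor_specific) + len(recipient_specific)
    if n_informative < min_positions:
        logger.info(
            "species %s excluded for pair %s: %d determinant position(s) < floor %d",
            species,
            pair_id,
            n_informative,
            min_positions,
        )
        return None
    return DeterminantSet(
        pair_id=pair_id,
        species_id=species,
        donor_specific=donor_specific,
        recipient_specific=recipient_specific,
        n_total_assessed=len(cov),
    )


@dataclass(frozen=True)
class RetentionPoint:
    donor_retention: float | None
    recipient_retention: float | None
    n_evaluable: int
    reason: str = ""


def _retained_fraction(positions: pd.Index, state: pd.Series) -> tuple[float | None, int]:
    if len(positions) == 0:
        return None, 0
    calls = state.loc[positions].to_numpy()
    evaluable = calls != UNRESOLVED
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        return None, 0
    return float((calls[evaluable] == PRESENT).sum() / n_eval), n_eval


def retention_fraction(
    dset: DeterminantSet,
    snv,
    post_sample: str,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> RetentionPoint:
    """Fraction of determinant alleles still observed in a post-FMT sample.

    donor_retention = (#donor-specific positions present) / (#donor-specific
    positions resolvable in the post sample); recipient_retention analogous.
    Positions unresolved post-FMT drop out of numerator and denominator.
    """
    if dset.n_determinant == 0:
        raise UndefinedInputError("determinant set is empty")
    cov, freq = snv.species_slice(dset.species_id)
    if post_sample not in cov.columns:
        raise ValidationError(f"sample {post_sample!r} absent from SNV table")
    state = pd.Series(
        call_presence_array(cov[post_sample].to_numpy(), freq[post_sample].to_numpy(), thresholds),
        index=cov.index,
    )
    donor_ret, n_d = _retained_fraction(dset.donor_specific, state)
    recip_ret, n_r = _retained_fraction(dset.recipient_specific, state)
    n_eval = n_d + n_r
    if n_eval == 0:
        return RetentionPoint(None, None, 0, reason="all determinant positions unresolved")
    return RetentionPoint(donor_ret, recip_ret, n_eval)


def classify_state(
    donor_retention: float | None,
    recipient_retention: float | None,
    hi: float = 0.8,
    lo: float = 0.2,
) -> str:
    """Displacement/coexistence call from the two retention fractions.

    coexistence when both retentions are at least ``lo``; donor_takeover
    when donor retention reaches ``hi`` with recipient below ``lo``;
    recipient_persistence symmetrically; otherwise indeterminate (including
    any missing retention).
    """
    if not 0 <= lo < hi <= 1:
        raise ValidationError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if donor_retention is None or recipient_retention is None:
        return "indeterminate"
    if donor_retention >= lo and recipient_retention >= lo:
        return "coexistence"
    if donor_retention >= hi and recipient_retention < lo:
        return "donor_takeover"
    if recipient_retention >= hi and donor_retention < lo:
        return "recipient_persistence"
    return "indeterminate"


def new_snv_rate(
    snv,
    recipient_baseline_sample: str,
    post_sample: str,
    thresholds: PresenceThresholds = PresenceThresholds(),
) -> tuple[float | None, pd.Series]:
    """Rate of alleles absent at baseline but present post-FMT.

    Computed over positions resolvable in *both* samples.  Returns
    (pooled rate, per-species rates); the pooled rate is None when no
    position is evaluable in both samples.
    """
    base_state = call_presence_array(
        snv.coverage[recipient_baseline_sample].to_numpy(),
        snv.freq[recipient_baseline_sample].to_numpy(),
        thresholds,
    )
    post_state = call_presence_array(
        snv.coverage[post_sample].to_numpy(), snv.freq[post_sample].to_numpy(), thresholds
    )
    evaluable = (base_state != UNRESOLVED) & (post_state != UNRESOLVED)
    new = evaluable & (base_state == ABSENT) & (post_state == PRESENT)
    species = snv.loci.index.get_level_values(0)
    per_species = {}
    for sp in sorted(set(species)):
        mask = (species == sp) & evaluable
        n = int(mask.sum())
        per_species[sp] = float(new[mask].sum() / n) if n else np.nan
    pooled = float(new.sum() / evaluable.sum()) if evaluable.any() else None
    return pooled, pd.Series(per_species, name="new_snv_rate")


def track_cohort(
    snv,
    manifest,
    thresholds: PresenceThresholds = PresenceThresholds(),
    min_positions: int = 20,
    hi: float = 0.8,
    lo: float = 0.2,
) -> pd.DataFrame:
    """Retention series for every allogenic pair, species and time point.

    Columns: pair_id, subtype, species_id, day, donor_retention,
    recipient_retention, n_evaluable, classification.
    """
    rows = []
    for pair in manifest.pairs():
        if pair.donor_sample is None or pair.baseline_sample is None:
            continue
        if pair.donor_sample not in snv.sample_ids or pair.baseline_sample not in snv.sample_ids:
            continue
        for species in snv.species_ids:
            dset = build_determinant_set(
                snv,
                pair.donor_sample,
                pair.baseline_sample,
                species,
                thresholds,
                min_positions,
                pair_id=pair.recipient,
            )
            if dset is None:
                continue
            for day, sample_id in pair.post_samples.items():
                if sample_id not in snv.sample_ids:
                    continue
                point = retention_fraction(dset, snv, sample_id, thresholds)
                rows.append(
                    {
                        "pair_id": pair.recipient,
                        "subtype": pair.subtype,
                        "species_id": species,
                        "day": day,
                        "donor_retention": point.donor_retention,
                        "recipient_retention": point.recipient_retention,
                        "n_evaluable": point.n_evaluable,
                        "classification": classify_state(
                            point.donor_retention, point.recipient_retention, hi, lo
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "subtype",
            "species_id",
            "day",
            "donor_retention",
            "recipient_retention",
            "n_evaluable",
            "classification",
        ],
    )


def cohort_retention_summary(series: pd.DataFrame, which: str = "donor_retention") -> pd.DataFrame:
    """Mean +/- sample SD of retention per (subtype, day), across recipients.

    Averaging is two-level: each recipient's species retentions are averaged
    first, then the mean and SD are taken across recipients, so recipients
    with many trackable species do not dominate.  Empty cells are omitted.
    A pooled-positions variant is also emitted (``pooled_mean``) because the
    per-recipient and pooled denominators answer slightly different
    questions.
    """
    if which not in ("donor_retention", "recipient_retention"):
        raise ValidationError(f"unknown retention column {which!r}")
    if series.empty:
        return pd.DataFrame(columns=["subtype", "day", "mean", "sd", "n_recipients", "pooled_mean"])
    df = series.dropna(subset=[which])
    rows = []
    for (subtype, day), cell in df.groupby(["subtype", "day"], sort=True):
        per_recipient = cell.groupby("pair_id")[which].mean()
        n = len(per_recipient)
        pooled = float(
            np.average(cell[which], weights=cell["n_evaluable"])
        )  # position-weighted alternative denominator
        rows.append(
            {
                "subtype": subtype,
                "day": int(day),
                "mean": float(per_recipient.mean()),
                "sd": float(per_recipient.std(ddof=1)) if n > 1 else 0.0,
                "n_recipients": n,
                "pooled_mean": pooled,
            }
        )
    return pd.DataFrame(rows)


def classification_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Fraction of tracked species per classification, by subtype and day."""
    if series.empty:
        return pd.DataFrame(columns=["subtype", "day", *CLASSIFICATIONS])
    rows = []
    for (subtype, day), cell in series.groupby(["subtype", "day"], sort=True):
        counts = cell["classification"].value_counts()
        total = len(cell)
        row = {"subtype": subtype, "day": int(day)}
        for c in CLASSIFICATIONS:
            row[c] = float(counts.get(c, 0) / total)
        rows.append(row)
    return pd.DataFrame(rows)
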