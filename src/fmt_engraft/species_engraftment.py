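"""Source partitioning of post-FMT communities.

Each taxon detected in a post-FMT sample (relative abundance >= 0.001 by
default; the gate is inclusive) is assigned to one of four disjoint source
categories by comparing detection in the donor and in the recipient's
baseline sample:

* ``donor_specific``   — detected in the donor, not at baseline;
* ``recipient_specific`` — detected at baseline, not in the donor;
* ``common``           — detected in both;
* ``new``              — detected in neither.

Per-sample fractions are reported both as taxon counts and as abundance
mass (renormalised over the detected post-FMT taxa); cohort summaries give
the mean and sample SD of the donor-specific fraction per disease subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedInputError, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("donor_specific", "recipient_specific", "common", "new")

DEFAULT_DETECTION_THRESHOLD = 0.001


def detect(profile: pd.Series, threshold: float = DEFAULT_DETECTION_THRESHOLD) -> set:
    """Taxa with relative abundance >= threshold ('at least', inclusive)."""
    if not 0 < threshold < 1:
        raise ValidationError(f"detection threshold must be in (0, 1), got {threshold}")
    profile = pd.Series(profile)
    return set(profile.index[profile.to_numpy(dtype=float) >= threshold])


@dataclass
class SpeciesPartition:
    """Four-way source partition of one post-FMT sample."""

    sample_id: str
    categories: Mapping[str, str]  # taxon -> category
    count_fractions: Mapping[str, float]
    abundance_fractions: Mapping[str, float]
    detection_threshold: float
    n_detected: int = field(default=0)

    def __post_init__(self) -> None:
        for fracs in (self.count_fractions, self.abundance_fractions):
            total = sum(fracs[c] for c in CATEGORIES)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"partition fractions sum to {total}, not 1")


def partition_sample(
    donor: pd.Series,
    pre: pd.Series,
    post: pd.Series,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    sample_id: str = "",
) -> SpeciesPartition:
    """Partition the detected taxa of a post-FMT profile by source.

    All three profiles share a taxon index; the detection gate is applied
    uniformly to donor, baseline and post vectors.  Fractions are computed
    over detected post-FMT taxa only, with abundance fractions renormalised
    to the detected mass.
    """
    donor, pre, post = pd.Series(donor), pd.Series(pre), pd.Series(post)
    if not (donor.index.equals(pre.index) and pre.index.equals(post.index)):
        raise ValidationError("donor, pre and post must share one taxon index")
    donor_set = detect(donor, threshold)
    pre_set = detect(pre, threshold)
    post_set = detect(post, threshold)
    if not post_set:
        raise UndefinedInputError("no taxon detected in the post-FMT profile")

    categories: dict[str, str] = {}
    for taxon in sorted(post_set):  # sorted so float accumulation is run-order independent
        in_donor = taxon in donor_set
        in_pre = taxon in pre_set
        if in_donor and in_pre:
            cat = "common"
        elif in_donor:
            cat = "donor_specific"
        elif in_pre:
            cat = "recipient_specific"
        else:
            cat = "new"
        categories[taxon] = cat

    counts = {c: 0 for c in CATEGORIES}
    mass = {c: 0.0 for c in CATEGORIES}
    for taxon, cat in categories.items():
        counts[cat] += 1
        mass[cat] += float(post[taxon])
    n = len(categories)
    total_mass = sum(mass.values())
    count_fractions = {c: counts[c] / n for c in CATEGORIES}
    abundance_fractions = {c: mass[c] / total_mass for c in CATEGORIES}
    return SpeciesPartition(
        sample_id=sample_id,
        categories=categories,
        count_fractions=count_fractions,
        abundance_fractions=abundance_fractions,
        detection_threshold=threshold,
        n_detected=n,
    )


def donor_gain_summary(
    partitions: Iterable[tuple[str, SpeciesPartition]],
    kind: str = "abundance",
    category: str = "donor_specific",
) -> pd.DataFrame:
    """Mean and sample SD of a source fraction per subtype and overall.

    ``partitions`` yields (subtype, partition) pairs; ``kind`` picks the
    count- or abundance-weighted fraction.  SD uses the n-1 denominator and
    is reported as 0.0 with ``n_is_one`` flagged when a group has a single
    member.  Empty groups are simply absent.
    """
    if kind not in ("abundance", "count"):
        raise ValidationError(f"kind must be 'abundance' or 'count', got {kind!r}")
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    rows = []
    for subtype, part in partitions:
        fracs = part.abundance_fractions if kind == "abundance" else part.count_fractions
        rows.append({"group": subtype, "fraction": fracs[category]})
    if not rows:
        logger.warning("donor_gain_summary called with no partitions")
        return pd.DataFrame(columns=["group", "mean", "sd", "n", "n_is_one"])
    df = pd.DataFrame(rows)
    df = pd.concat([df, df.assign(group="overall")], ignore_index=True)

    def _agg(grp: pd.Series) -> pd.Series:
        n = len(grp)
        return pd.Series(
            {
                "mean": float(grp.mean()),
                "sd": float(grp.std(ddof=1)) if n > 1 else 0.0,
                "n": n,
                "n_is_one": n == 1,
            }
        )

    out = df.groupby("group", sort=True)["fraction"].apply(_agg).unstack()
    out = out.reset_index()
    out["n"] = out["n"].astype(int)
    out["n_is_one"] = out["n_is_one"].astype(bool)
    return out


def partition_cohort(
    abundance, manifest, threshold: float = DEFAULT_DETECTION_THRESHOLD
) -> list[tuple[str, int, SpeciesPartition]]:
    """Partition every post-FMT sample in a cohort.

    Returns (subtype, day, partition) triples; each post sample is compared
    against the same (donor, baseline) pair of its recipient.  Pairs with a
    missing donor or baseline sample are skipped with a logged reason.
    """
    out = []
    for pair in manifest.pairs():
        if pair.donor_sample is None or pair.baseline_sample is None:
            logger.info("skipping %s: missing donor or baseline sample", pair.recipient)
            continue
        donor = abundance.sample(pair.donor_sample)
        pre = abundance.sample(pair.baseline_sample)
        for day, sample_id in pair.post_samples.items():
            post = abundance.sample(sample_id)
            part = partition_sample(donor, pre, post, threshold, sample_id=sample_id)
            out.append((pair.subtype, day, part))
    return out


def partitions_long_table(parts: Iterable[tuple[str, int, SpeciesPartition]]) -> pd.DataFrame:
    """Long-format (sample, taxon, category) table for TSV export."""
    rows = []
    for subtype, day, part in parts:
        for taxon, cat in sorted(part.categories.items()):
            rows.append(
                {
                    "sample_id": part.sample_id,
                    "subtype": subtype,
                    "day": day,
                    "taxon_id": taxon,
                    "category": cat,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "subtype", "day", "taxon_id", "category"])
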