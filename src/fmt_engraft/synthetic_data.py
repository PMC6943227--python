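"""Synthetic FMT cohorts with known ground truth.

The generator emulates the *profiled outputs* of a shotgun FMT study — not
reads: sparse compositional species profiles for donors and recipients,
post-FMT communities mixed from donor, recipient and environmental mass
with a controlled donor fraction, biallelic SNV tables with controlled
strain displacement under binomial read sampling, and clinical index
tables with optionally planted rank correlations against taxon changes.
Every quantity the downstream modules estimate is bookkept exactly, so
recovery can be tested without any real cohort.

Default cohort shape mirrors a small single-centre IBD trial: 15
donor–recipient pairs (11 Crohn's disease, 4 ulcerative colitis) sharing 6
healthy donors, visits at days 3, 7 and 30, post-FMT communities drawing
~30% of their mass from the donor, and subtype-specific strain
displacement (UC recipients far more permissive than CD).  All randomness
flows from the spec's seed; identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import SimSpecError
from .types import AbundanceTable, ClinicalTable, CohortManifest, SNVTable

ENV_POOL_FRACTION = 0.15  # taxa reserved as 'environmental', never in donors/recipients


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise SimSpecError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortSimSpec:
    """Species-level cohort simulation parameters.

    d is the post-FMT mass fraction drawn from the donor, g the fraction
    from environmental taxa seen in neither donor nor recipient; the
    remaining 1-d-g comes from the recipient's baseline community.
    """

    n_pairs: int = 15
    n_taxa: int = 200
    species_engraftment: float = 0.3  # d
    env_gain: float = 0.05  # g
    sparsity: float = 0.5
    timepoints: Sequence[int] = (3, 7, 30)
    n_donors: int | None = None
    cd_fraction: float = 11 / 15
    seed: int = 0

    def __post_init__(self) -> None:
        _check_fraction("species_engraftment", self.species_engraftment)
        _check_fraction("env_gain", self.env_gain)
        _check_fraction("sparsity", self.sparsity)
        _check_fraction("cd_fraction", self.cd_fraction)
        if self.species_engraftment + self.env_gain > 1:
            raise SimSpecError("species_engraftment + env_gain must be <= 1")
        if self.n_taxa < 4:
            raise SimSpecError("n_taxa must be >= 4")
        if self.n_pairs < 1:
            raise SimSpecError("n_pairs must be >= 1")
        if any(int(t) <= 0 for t in self.timepoints):
            raise SimSpecError("timepoints must be positive day offsets")


@dataclass
class SpeciesCohortTruth:
    """Exact bookkeeping of the species-level simulation.

    per_sample rows: recipient, day, sample_id, d, g and the exact
    abundance-weighted source fractions of the mixed community (computed
    from the true supports, before any detection threshold).
    """

    per_sample: pd.DataFrame
    supports: dict[str, set] = field(default_factory=dict)


def build_manifest(spec: CohortSimSpec) -> CohortManifest:
    """Donor/recipient manifest for the simulated cohort.

    Recipients are labelled with their disease subtype as a prefix (CD-1,
    UC-2, ...); donors are shared cyclically so several recipients can
    receive material from the same donor.
    """
    n_cd = int(round(spec.n_pairs * spec.cd_fraction))
    subtypes = ["CD"] * n_cd + ["UC"] * (spec.n_pairs - n_cd)
    n_donors = spec.n_donors or max(1, int(round(spec.n_pairs * 6 / 15)))
    donors = [f"D{i + 1}" for i in range(n_donors)]
    rows = []
    for don in donors:
        rows.append(
            {
                "sample_id": f"{don}.don",
                "subject_id": don,
                "role": "donor",
                "donor_id": "",
                "subtype": "healthy",
                "arm": "none",
                "day": 0,
            }
        )
    counters = {"CD": 0, "UC": 0}
    for i, subtype in enumerate(subtypes):
        counters[subtype] += 1
        subject = f"{subtype}-{counters[subtype]}"
        donor = donors[i % n_donors]
        for day in (0, *spec.timepoints):
            rows.append(
                {
                    "sample_id": f"{subject}.d{int(day)}",
                    "subject_id": subject,
                    "role": "recipient",
                    "donor_id": donor,
                    "subtype": subtype,
                    "arm": "allogenic",
                    "day": int(day),
                }
            )
    return CohortManifest(pd.DataFrame(rows))


def _subject_profile(rng: np.random.Generator, pool: np.ndarray, n_taxa: int, sparsity: float):
    """Sparse log-normal profile over ``pool``; returns dense length-n_taxa."""
    include = rng.random(pool.size) < (1.0 - sparsity)
    if not include.any():
        include[rng.integers(pool.size)] = True
    profile = np.zeros(n_taxa)
    magnitudes = rng.lognormal(mean=0.0, sigma=1.0, size=int(include.sum()))
    profile[pool[include]] = magnitudes
    return profile / profile.sum()


def simulate_species_cohort(
    spec: CohortSimSpec,
) -> tuple[AbundanceTable, CohortManifest, SpeciesCohortTruth]:
    """Generate donor, baseline and post-FMT abundance profiles.

    Donor and recipient baselines are independent sparse log-normal
    profiles over a shared taxon pool; the post-FMT profile at every
    timepoint is the renormalised mixture d*donor + (1-d-g)*recipient +
    g*environment, where environmental taxa come from a reserved pool
    absent from every donor and baseline.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = build_manifest(spec)
    taxa = [f"T{i + 1:04d}" for i in range(spec.n_taxa)]
    n_env = max(1, math.ceil(ENV_POOL_FRACTION * spec.n_taxa)) if spec.env_gain > 0 else 0
    main_pool = np.arange(spec.n_taxa - n_env)
    env_pool = np.arange(spec.n_taxa - n_env, spec.n_taxa)

    columns: dict[str, np.ndarray] = {}
    supports: dict[str, set] = {}
    d, g = spec.species_engraftment, spec.env_gain

    donor_profiles: dict[str, np.ndarray] = {}
    for don in manifest.donor_subjects:
        prof = _subject_profile(rng, main_pool, spec.n_taxa, spec.sparsity)
        donor_profiles[don] = prof
        columns[f"{don}.don"] = prof
        supports[don] = {taxa[i] for i in np.nonzero(prof)[0]}

    truth_rows = []
    for pair in manifest.pairs():
        recipient = pair.recipient
        base = _subject_profile(rng, main_pool, spec.n_taxa, spec.sparsity)
        columns[pair.baseline_sample] = base
        supports[recipient] = {taxa[i] for i in np.nonzero(base)[0]}
        donor = donor_profiles[pair.donor]
        if g > 0:
            env = _subject_profile(rng, env_pool, spec.n_taxa, 0.5)
        else:
            env = np.zeros(spec.n_taxa)
        supports[f"{recipient}:env"] = {taxa[i] for i in np.nonzero(env)[0]}
        post = d * donor + (1.0 - d - g) * base + g * env
        post = post / post.sum()

        donor_only = (donor > 0) & (base <= 0)
        recip_only = (base > 0) & (donor <= 0)
        common = (donor > 0) & (base > 0)
        new = env > 0
        for day, sample_id in pair.post_samples.items():
            columns[sample_id] = post
            truth_rows.append(
                {
                    "recipient": recipient,
                    "subtype": pair.subtype,
                    "day": day,
                    "sample_id": sample_id,
                    "d": d,
                    "g": g,
                    "frac_donor_specific": float(post[donor_only].sum()),
                    "frac_recipient_specific": float(post[recip_only].sum()),
                    "frac_common": float(post[common].sum()),
                    "frac_new": float(post[new].sum()),
                }
            )

    ordered = [s for s in manifest.records["sample_id"] if s in columns]
    data = pd.DataFrame({s: columns[s] for s in ordered}, index=pd.Index(taxa, name="taxon_id"))
    table = AbundanceTable(data)
    truth = SpeciesCohortTruth(per_sample=pd.DataFrame(truth_rows), supports=supports)
    return table, manifest, truth


# ---------------------------------------------------------------------------
# strain level


@dataclass(frozen=True)
class StrainSimSpec:
    """SNV cohort simulation parameters.

    displacement f: probability that a donor-specific determinant allele is
    established in the recipient post-FMT; may be a single fraction or a
    per-subtype mapping.  recipient_retention r: probability an indigenous
    recipient allele persists.  Reads are sampled binomially around
    ``mean_coverage`` with a per-read miscall probability ``error_rate``
    (miscalls land on the specific alternative base one third of the time).
    """

    n_species: int = 50
    positions_per_species: int = 100
    displacement: float | Mapping[str, float] = field(
        default_factory=lambda: {"CD": 0.11, "UC": 0.63}
    )
    recipient_retention: float | Mapping[str, float] = 0.8
    mean_coverage: float = 20.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positions_per_species < 20:
            raise SimSpecError(
                "positions_per_species must be >= 20 (the strain-tracking inclusion floor)"
            )
        if self.n_species < 1:
            raise SimSpecError("n_species must be >= 1")
        if self.mean_coverage <= 0:
            raise SimSpecError("mean_coverage must be > 0")
        _check_fraction("error_rate", self.error_rate)
        for name, value in (
            ("displacement", self.displacement),
            ("recipient_retention", self.recipient_retention),
        ):
            if isinstance(value, Mapping):
                for k, v in value.items():
                    _check_fraction(f"{name}[{k}]", v)
            else:
                _check_fraction(name, value)

    def rate_for(self, which: str, subtype: str) -> float:
        value = self.displacement if which == "f" else self.recipient_retention
        if isinstance(value, Mapping):
            if subtype not in value:
                raise SimSpecError(f"no {which} rate configured for subtype {subtype!r}")
            return float(value[subtype])
        return float(value)


def _observed_freq(
    rng: np.random.Generator, allele: np.ndarray, coverage: np.ndarray, error_rate: float
) -> np.ndarray:
    """Alt-allele frequency under binomial read sampling with miscalls.

    A read from the alt allele reports alt with prob 1 - e; a read from the
    ref allele miscalls to the specific alt base with prob e/3.
    """
    p_alt = np.where(allele > 0, 1.0 - error_rate, error_rate / 3.0)
    alt_reads = rng.binomial(coverage, p_alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(coverage > 0, alt_reads / np.maximum(coverage, 1), np.nan)
    return freq


def simulate_snv_cohort(
    spec: StrainSimSpec, manifest: CohortManifest
) -> tuple[SNVTable, pd.DataFrame]:
    """Generate a biallelic SNV table with planted strain displacement.

    Per species, the first half of the positions carries the donor strain's
    alternative allele (present in every donor, absent from every recipient
    baseline) and the second half the recipient strains' alleles.  In each
    recipient's post-FMT samples, a donor allele is established with
    probability f and an indigenous allele persists with probability r;
    the established/lost state is drawn once per position and held across
    timepoints.  Returns the table plus a truth frame with the planted and
    realised fractions per (pair, species).
    """
    pairs = [p for p in manifest.pairs() if p.arm == "allogenic" and p.donor_sample]
    if not pairs:
        raise SimSpecError("manifest must contain at least one allogenic pair")
    rng = np.random.default_rng(spec.seed)
    P = spec.positions_per_species
    n_donor_pos = P // 2
    species_ids = [f"S{i + 1:03d}" for i in range(spec.n_species)]

    idx = pd.MultiIndex.from_product(
        [species_ids, range(P)], names=["species_id", "position"]
    )
    n_loci = len(idx)
    donor_allele = np.zeros(n_loci, dtype=np.int8)  # alt carried by the donor strain
    recip_allele = np.zeros(n_loci, dtype=np.int8)
    per_species_pos = np.tile(np.arange(P), spec.n_species)
    donor_allele[per_species_pos < n_donor_pos] = 1
    recip_allele[per_species_pos >= n_donor_pos] = 1

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_loci)]
    alt = bases[(np.array([list("ACGT").index(b) for b in ref]) + rng.integers(1, 4, n_loci)) % 4]
    loci = pd.DataFrame({"ref_allele": ref, "alt_allele": alt}, index=idx)

    cov_cols: dict[str, np.ndarray] = {}
    freq_cols: dict[str, np.ndarray] = {}

    def _sample(allele: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        coverage = rng.poisson(spec.mean_coverage, n_loci)
        return coverage, _observed_freq(rng, allele, coverage, spec.error_rate)

    seen_donor_samples: set[str] = set()
    truth_rows = []
    for pair in pairs:
        if pair.donor_sample not in seen_donor_samples:
            cov, fr = _sample(donor_allele)
            cov_cols[pair.donor_sample] = cov
            freq_cols[pair.donor_sample] = fr
            seen_donor_samples.add(pair.donor_sample)
        if pair.baseline_sample is None:
            continue
        cov, fr = _sample(recip_allele)
        cov_cols[pair.baseline_sample] = cov
        freq_cols[pair.baseline_sample] = fr

        f = spec.rate_for("f", pair.subtype)
        r = spec.rate_for("r", pair.subtype)
        established = rng.random(n_loci) < f  # donor alleles that engraft
        persisted = rng.random(n_loci) < r  # indigenous alleles that remain
        post_allele = (donor_allele & established) | (recip_allele & persisted)
        for _, sample_id in pair.post_samples.items():
            cov, fr = _sample(post_allele.astype(np.int8))
            cov_cols[sample_id] = cov
            freq_cols[sample_id] = fr
        for si, sp in enumerate(species_ids):
            block = slice(si * P, (si + 1) * P)
            d_mask = donor_allele[block] == 1
            r_mask = recip_allele[block] == 1
            truth_rows.append(
                {
                    "pair_id": pair.recipient,
                    "subtype": pair.subtype,
                    "species_id": sp,
                    "f": f,
                    "r": r,
                    "realized_donor_fraction": float(established[block][d_mask].mean()),
                    "realized_recipient_fraction": float(persisted[block][r_mask].mean()),
                }
            )

    samples = list(cov_cols)
    snv = SNVTable(
        loci=loci,
        coverage=pd.DataFrame({s: cov_cols[s] for s in samples}, index=idx),
        freq=pd.DataFrame({s: freq_cols[s] for s in samples}, index=idx),
    )
    return snv, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# clinical


DEFAULT_CLINICAL_INDEXES = (
    "HBI",
    "Mayo",
    "CD4_CD8_ratio",
    "IgA",
    "defecation_score",
    "CRP",
    "Th_cell_induced",
    "BMI",
    "age",
    "disease_duration",
)


def simulate_clinical(
    manifest: CohortManifest,
    effect_map: Mapping[tuple[str, str], float] | None,
    abundance: AbundanceTable,
    index_names: Sequence[str] = DEFAULT_CLINICAL_INDEXES,
    seed: int = 0,
    days: tuple[int, int] = (0, 3),
) -> ClinicalTable:
    """Clinical indexes with optionally planted taxon associations.

    For each (taxon, index) pair in ``effect_map`` the index *change*
    between the two visit days follows a Gaussian copula against that
    taxon's abundance change across recipients, targeting the requested
    Spearman correlation; all other indexes change independently.
    """
    effect_map = dict(effect_map or {})
    for (taxon, index), rho in effect_map.items():
        if not -1.0 <= rho <= 1.0:
            raise SimSpecError(f"requested |rho| > 1 for ({taxon}, {index}): {rho}")
        if index not in index_names:
            raise SimSpecError(f"effect on unknown index {index!r}")
        if taxon not in abundance.data.index:
            raise SimSpecError(f"effect on unknown taxon {taxon!r}")
    planted_by_index: dict[str, tuple[str, float]] = {}
    for (taxon, index), rho in effect_map.items():
        if index in planted_by_index:
            raise SimSpecError(f"more than one planted taxon for index {index!r}")
        planted_by_index[index] = (taxon, rho)

    rng = np.random.default_rng(seed)
    t1, t2 = days
    recipients = []
    deltas = {}
    for pair in manifest.pairs():
        s1 = pair.baseline_sample if t1 == 0 else manifest.sample_for(pair.recipient, t1)
        s2 = manifest.sample_for(pair.recipient, t2)
        if s1 is None or s2 is None:
            continue
        recipients.append(pair.recipient)
        deltas[pair.recipient] = abundance.data[s2] - abundance.data[s1]
    n = len(recipients)

    rows = []
    for index in index_names:
        baseline = rng.normal(0.0, 1.0, n)
        if index in planted_by_index and n >= 2:
            taxon, rho_s = planted_by_index[index]
            taxon_delta = np.array([deltas[r][taxon] for r in recipients])
            # Gaussian copula: Pearson r on normal scores giving Spearman rho_s
            r_pearson = 2.0 * math.sin(math.pi * rho_s / 6.0)
            ranks = scipy.stats.rankdata(taxon_delta)
            z = scipy.stats.norm.ppf((ranks - 0.5) / n)
            noise = rng.normal(0.0, 1.0, n)
            change = r_pearson * z + math.sqrt(max(0.0, 1.0 - r_pearson**2)) * noise
        else:
            change = rng.normal(0.0, 1.0, n)
        for i, subject in enumerate(recipients):
            rows.append(
                {"subject_id": subject, "day": t1, "index_name": index, "value": baseline[i]}
            )
            rows.append(
                {
                    "subject_id": subject,
                    "day": t2,
                    "index_name": index,
                    "value": baseline[i] + change[i],
                }
            )
    return ClinicalTable(pd.DataFrame(rows))
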