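"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every generator is fully deterministic given its seed and records its own
ground truth (probe-locus containment, causal CpG/locus sets, true
variance components), so downstream modules can be tested against known
answers without any external download.

The methylation model works on the logit scale so betas respect (0, 1):
causal probes follow ``logit(beta) = a_j + b_j * (driver - mean(driver))
+ noise`` where the driver is chronological age for human-style cohorts
and relative age ``ln(age + 2)`` for multi-species cohorts; non-causal
probes are age-independent.  Optional donor / tissue / species block
effects add shared shifts on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import BetaMatrix, ProbeRecord
from .retro_annotation import RetroLocus

_FAMILIES = {
    "HERV": ("HML2", "HERVH", "HERVK", "MER41"),
    "LINE": ("L1FLnI", "L1PA2", "L1HS"),
    "LTR": ("LTR7", "LTR12C"),
    "SINE": ("AluY", "AluSx"),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated cohorts.

    Defaults describe a desk-scale blood-methylation cohort: 600 samples,
    3000 retroelement probes of which 150 carry a logit-linear age effect
    of 0.02 logit units per year against logit noise of sd 0.5 — a
    per-probe signal-to-noise ratio near 1 over a 12-100 year age span.
    Multi-species cohorts (``n_species`` set) drive methylation with
    relative age ``ln(age + 2)`` at ``effect_scale_relative`` per log-year
    instead.
    """

    n_samples: int = 600
    n_probes: int = 3000
    n_causal: int = 150
    age_range: tuple[float, float] = (12.0, 100.0)
    effect_scale: float = 0.02            # logit units per year
    effect_scale_relative: float = 0.5    # logit units per ln-year (species mode)
    noise_sd_logit: float = 0.5
    baseline_sd_logit: float = 1.5
    n_donors: int | None = None
    n_tissues: int | None = None
    n_species: int | None = None
    donor_sd_logit: float = 0.1
    tissue_sd_logit: float = 0.1
    species_sd_logit: float = 0.2
    sigma2_between: float = 9.0           # replicate design, years^2
    sigma2_within: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValidationError("n_causal must be <= n_probes")
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError("age_range must satisfy min < max")
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValidationError("replicate variance components must be >= 0")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# manifest + annotation with known containment truth
# ---------------------------------------------------------------------------

def simulate_manifest_and_annotation(
    n_probes: int = 500,
    n_loci: int = 120,
    inside_fraction: float = 0.6,
    seed: int = 0,
    n_chroms: int = 3,
    chrom_length: int = 1_000_000,
    locus_length: tuple[int, int] = (500, 5_000),
) -> tuple[list[ProbeRecord], list[RetroLocus], pd.DataFrame]:
    """Random loci and probes with exact probe-locus containment truth.

    ``inside_fraction`` of the probes is placed inside a random locus, the
    rest strictly outside all loci.  The truth table (one row per
    containment pair, columns probe_id / locus_id / family / class) is
    computed by brute-force all-pairs containment so it holds even when a
    probe lands in several overlapping loci.
    """
    if not 0.0 <= inside_fraction <= 1.0:
        raise ValidationError("inside_fraction must be in [0, 1]")
    if inside_fraction > 0 and n_loci == 0:
        raise ValidationError("cannot place probes inside loci without loci")
    rng = np.random.default_rng(seed)
    classes = list(_FAMILIES)

    loci: list[RetroLocus] = []
    for i in range(n_loci):
        cls = classes[i % len(classes)]
        fam = _FAMILIES[cls][rng.integers(len(_FAMILIES[cls]))]
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        length = int(rng.integers(locus_length[0], locus_length[1] + 1))
        start = int(rng.integers(1, chrom_length - length))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(RetroLocus(
            f"{fam}_{chrom}_{i}", chrom, start, start + length - 1,
            strand, fam, cls,
        ))

    by_chrom: dict[str, list[RetroLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)

    def in_any_locus(chrom: str, pos: int) -> bool:
        return any(l.start <= pos <= l.end for l in by_chrom.get(chrom, []))

    n_inside = int(round(inside_fraction * n_probes))
    probes: list[ProbeRecord] = []
    for i in range(n_inside):
        locus = loci[int(rng.integers(len(loci)))]
        pos = int(rng.integers(locus.start, locus.end + 1))
        probes.append(ProbeRecord(f"cg{i:08d}", locus.chrom, pos))
    for i in range(n_inside, n_probes):
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            pos = int(rng.integers(1, chrom_length))
            if not in_any_locus(chrom, pos):
                probes.append(ProbeRecord(f"cg{i:08d}", chrom, pos))
                break
        else:
            raise ValidationError(
                "could not place a probe outside all loci; lower n_loci or "
                "locus_length"
            )

    rows = []
    for probe in probes:  # brute-force all-pairs: the oracle
        for locus in by_chrom.get(probe.chrom, []):
            if locus.start <= probe.pos <= locus.end:
                rows.append({
                    "probe_id": probe.probe_id, "locus_id": locus.locus_id,
                    "family": locus.family, "repeat_class": locus.repeat_class,
                })
    truth = pd.DataFrame(rows, columns=["probe_id", "locus_id", "family",
                                        "repeat_class"])
    return probes, loci, truth


# ---------------------------------------------------------------------------
# methylation cohorts
# ---------------------------------------------------------------------------

def simulate_methylation_cohort(
    config: SyntheticConfig,
) -> tuple[BetaMatrix, pd.DataFrame, list[str]]:
    """Simulate a beta matrix, sample metadata and the causal CpG set.

    Human-style cohorts draw ages uniformly over ``age_range``; species
    cohorts (``n_species`` set) draw each species' lifespan scale
    log-uniformly over [0.1, 1] of the configured maximum and drive the
    causal probes with relative age ``ln(age + 2)``, so the log-offset
    response transform is the correct model.  With ``n_donors`` set,
    samples are nested in donors (all samples of a donor share its age and
    a donor-level logit shift) — the structure donor-grouped splitting
    must respect.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_probes
    sample_ids = [f"S{i:05d}" for i in range(n)]
    probe_ids = [f"cg{j:08d}" for j in range(p)]

    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    species_mode = cfg.n_species is not None and cfg.n_species > 1

    if cfg.n_donors:
        donors = np.array([f"D{i % cfg.n_donors:05d}" for i in range(n)])
        meta["donor_id"] = donors
        donor_labels = sorted(set(donors))
        if species_mode:
            species_of_donor = {
                d: f"sp{k % cfg.n_species:03d}" for k, d in enumerate(donor_labels)
            }
            meta["species"] = [species_of_donor[d] for d in donors]
        scales = {}
        if species_mode:
            for s in sorted(set(meta["species"])):
                scales[s] = 10 ** rng.uniform(-1, 0)
        donor_age = {}
        for d in donor_labels:
            lo, hi = cfg.age_range
            if species_mode:
                hi = lo + (hi - lo) * scales[species_of_donor[d]]
                lo = 0.0
            donor_age[d] = rng.uniform(lo, hi)
        meta["age"] = [donor_age[d] for d in donors]
        donor_shift = {d: rng.normal(0, cfg.donor_sd_logit) for d in donor_labels}
        block = np.array([donor_shift[d] for d in donors])
    else:
        if species_mode:
            species = np.array([f"sp{i % cfg.n_species:03d}" for i in range(n)])
            meta["species"] = species
            scales = {s: 10 ** rng.uniform(-1, 0)
                      for s in sorted(set(species))}
            lo, hi = cfg.age_range
            meta["age"] = [rng.uniform(0.0, lo + (hi - lo) * scales[s])
                           for s in species]
        else:
            meta["age"] = rng.uniform(*cfg.age_range, size=n)
        block = np.zeros(n)

    if cfg.n_tissues:
        tissues = [f"tissue{i % cfg.n_tissues}" for i in range(n)]
        meta["tissue"] = tissues
        tshift = {t: rng.normal(0, cfg.tissue_sd_logit)
                  for t in sorted(set(tissues))}
        block = block + np.array([tshift[t] for t in tissues])
    if species_mode:
        sshift = {s: rng.normal(0, cfg.species_sd_logit)
                  for s in sorted(set(meta["species"]))}
        block = block + np.array([sshift[s] for s in meta["species"]])

    ages = meta["age"].to_numpy(dtype=float)
    driver = np.log(ages + 2.0) if species_mode else ages
    driver_c = driver - driver.mean()
    effect = cfg.effect_scale_relative if species_mode else cfg.effect_scale

    causal_idx = rng.choice(p, size=cfg.n_causal, replace=False)
    causal_idx.sort()
    signs = rng.choice([-1.0, 1.0], size=cfg.n_causal)
    slopes = np.zeros(p)
    slopes[causal_idx] = signs * effect

    baseline = rng.normal(0.0, cfg.baseline_sd_logit, size=p)
    noise = rng.normal(0.0, cfg.noise_sd_logit, size=(p, n))
    logits = baseline[:, None] + slopes[:, None] * driver_c[None, :] \
        + block[None, :] + noise
    betas = _logistic(logits)

    beta = BetaMatrix(pd.DataFrame(betas, index=probe_ids, columns=sample_ids))
    causal = [probe_ids[j] for j in causal_idx]
    return beta, meta, causal


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------

def simulate_replicates(
    n_subjects: int = 30,
    n_replicates: int = 2,
    sigma2_between: float = 9.0,
    sigma2_within: float = 1.0,
    mean_age: float = 55.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Predicted ages with replicate structure and known true ICC.

    Subject means ~ N(mean_age, sigma2_between); replicates ~
    N(subject mean, sigma2_within).  Returns (predictions, metadata,
    true ICC); metadata's ``replicate_of`` column names each sample's
    subject.
    """
    if sigma2_between < 0 or sigma2_within < 0:
        raise ValidationError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    subject_means = mean_age + np.sqrt(sigma2_between) * rng.standard_normal(n_subjects)
    rows = []
    for i in range(n_subjects):
        for r in range(n_replicates):
            value = subject_means[i] + np.sqrt(sigma2_within) * rng.standard_normal()
            rows.append({
                "sample_id": f"R{i:03d}_{r}",
                "replicate_of": f"SUBJ{i:03d}",
                "predicted_age": value,
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    predictions = df[["predicted_age"]].copy()
    predictions["n_missing_probes"] = 0
    predictions["imputed_fraction"] = 0.0
    metadata = df[["replicate_of"]].copy()
    metadata["age"] = mean_age
    total = sigma2_between + sigma2_within
    true_icc = sigma2_between / total if total > 0 else 0.0
    return predictions, metadata, true_icc


# ---------------------------------------------------------------------------
# retroelement expression cohorts
# ---------------------------------------------------------------------------

def simulate_expression_cohort(
    n_samples: int = 160,
    n_loci: int = 1000,
    n_causal: int = 40,
    age_range: tuple[float, float] = (20.0, 74.0),
    effect_scale: float = 0.02,      # log-fold change per year
    dispersion: float = 10.0,        # NB size parameter
    mean_library_size: float = 1e6,
    library_sd_log: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Negative-binomial retroelement expression counts with age signal.

    Causal loci have log-mean linear in (centered) age; library sizes are
    log-normal.  Returns (counts loci x samples, metadata, causal loci).
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"E{i:04d}" for i in range(n_samples)]
    locus_ids = [f"locus{j:05d}" for j in range(n_loci)]
    ages = rng.uniform(*age_range, size=n_samples)
    lib = mean_library_size * np.exp(
        library_sd_log * rng.standard_normal(n_samples)
    )

    causal_idx = rng.choice(n_loci, size=n_causal, replace=False)
    causal_idx.sort()
    slopes = np.zeros(n_loci)
    slopes[causal_idx] = rng.choice([-1.0, 1.0], size=n_causal) * effect_scale
    base = rng.normal(np.log(50.0), 1.0, size=n_loci)  # mean count at 1M reads

    age_c = ages - ages.mean()
    log_mu = base[:, None] + slopes[:, None] * age_c[None, :] \
        + np.log(lib / mean_library_size)[None, :]
    mu = np.exp(log_mu)
    p_nb = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p_nb)

    counts_df = pd.DataFrame(counts, index=locus_ids, columns=sample_ids)
    meta = pd.DataFrame({"age": ages},
                        index=pd.Index(sample_ids, name="sample_id"))
    causal = [locus_ids[j] for j in causal_idx]
    return counts_df, meta, causal
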