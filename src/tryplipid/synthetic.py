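"""Synthetic measurement generators emulating the oleate feeding study.

Every input table the analysis pipeline consumes can be generated here
under a fixed seed: per-cell lipid-droplet (LD) counts, whole-cell
flow-cytometry fluorescence, TLC densitometry lanes, exponential growth
curves, post-withdrawal decay series, a shotgun-lipidomics TAG species
table with a spiked internal standard, a two-genotype label-free
proteome table, and the enzyme specific-activity summary table.

All outputs are tidy :class:`pandas.DataFrame` objects in the package's
delimited-text schemas (see :mod:`tryplipid.io`).  Identical
:class:`~tryplipid.config.StudyConfig` (including the seed) gives
byte-identical tables after serialization.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import StudyConfig

__all__ = [
    "gen_ld_counts",
    "gen_flow_population",
    "gen_growth_curve",
    "gen_decay_experiment",
    "gen_lipidome",
    "gen_proteome_table",
    "gen_activity_table",
    "gen_tlc_lane",
    "TLC_BANDS",
    "ABLATED_PROTEIN_ID",
]

# Independent RNG stream codes per dataset, combined with the config
# seed so that generating one table never perturbs another.
_STREAMS = {
    "ld": 11,
    "flow": 12,
    "growth": 13,
    "decay": 14,
    "lipidome": 15,
    "proteome": 16,
    "tlc": 17,
}

_CONDITIONS = ("fed", "unfed")

#: TLC band map: retardation factor and normalized base area per lipid
#: class.  Phospholipids stay at the origin; the TAG band (R_F 0.50) is
#: the quantified one.
TLC_BANDS = {
    "PL": (0.00, 5.0),
    "DAG": (0.08, 0.3),
    "FFA": (0.29, 0.5),
    "TAG": (0.50, 1.0),
    "SE": (0.90, 0.2),
}

ABLATED_PROTEIN_ID = "TFEA1"


def _rng(config: StudyConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream], *extra])


def _check_condition(condition: str) -> str:
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}, got {condition!r}")
    return condition


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _ld_count_params(config: StudyConfig, condition: str) -> tuple[int, float]:
    """Binomial (n, p) for the per-cell LD count in one condition.

    A binomial with n = ld_max gives the observed bell-shaped count
    distribution with bounded support — no cell can exceed the hard
    per-cell maximum — while the mean is set exactly to the target.
    """
    mean = config.fed_ld_mean if condition == "fed" else config.unfed_ld_mean
    p = mean / config.ld_max
    if not 0 < p <= 1:
        raise ValueError(
            f"target mean {mean:.3g} LDs/cell is inconsistent with ld_max={config.ld_max}"
        )
    return config.ld_max, p


def gen_ld_counts(
    config: StudyConfig, condition: str, replicate: int = 0
) -> pd.DataFrame:
    """Per-cell LD counts for one condition (microscopy counting).

    Returns a frame with columns ``cell_id, condition, count``.
    Counts are binomial(ld_max, p) with p chosen so the population mean
    is ``unfed_ld_mean`` (unfed) or ``unfed_ld_mean * ld_fold`` (fed).
    """
    _check_condition(condition)
    n, p = _ld_count_params(config, condition)
    rng = _rng(config, "ld", _CONDITIONS.index(condition), replicate)
    counts = rng.binomial(n, p, size=config.n_cells)
    return pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells),
            "condition": condition,
            "count": counts,
        }
    )


def _per_droplet_intensity(config: StudyConfig) -> float:
    """Mean fluorescence of a single droplet, in background units.

    Solved so that the fed/unfed population mean ratio equals
    ``flow_fold`` exactly in expectation:

        (B + m_fed * d) / (B + m_unfed * d) = flow_fold

    With zero background the ratio is the LD-count fold regardless of
    d, so d defaults to 1.
    """
    b = config.flow_background
    f = config.flow_fold
    m_u = config.unfed_ld_mean
    m_f = config.fed_ld_mean
    if b == 0:
        return 1.0
    denom = m_f - f * m_u
    if denom <= 0:
        # f == 1 gives d = 0 (no droplet signal); f in (1, ld_fold) is
        # enforced by StudyConfig validation.
        return 0.0 if f <= 1 else float("nan")
    return b * (f - 1.0) / denom


def gen_flow_population(
    config: StudyConfig,
    condition: str,
    replicate: int = 0,
    counts: np.ndarray | None = None,
    droplet_intensity_mean: float | None = None,
) -> pd.DataFrame:
    """Whole-cell fluorescence population for one condition.

    Each cell's signal is background plus the summed emission of its
    droplets (per-droplet brightness lognormal, CV 0.25), times
    multiplicative measurement noise of CV ``noise_cv``; the cytometer
    integrates the whole cell, so background is never subtracted.

    Returns a frame with columns ``cell_id, condition, intensity``.
    """
    _check_condition(condition)
    rng = _rng(config, "flow", _CONDITIONS.index(condition), replicate)
    if counts is None:
        n, p = _ld_count_params(config, condition)
        counts = rng.binomial(n, p, size=config.n_cells)
    else:
        counts = np.asarray(counts, dtype=int)
        if counts.min() < 0:
            raise ValueError("droplet counts must be >= 0")
    d = (
        _per_droplet_intensity(config)
        if droplet_intensity_mean is None
        else droplet_intensity_mean
    )
    n_cells = counts.size
    max_count = int(counts.max()) if n_cells else 0
    if max_count > 0 and d > 0:
        per_droplet = d * _lognormal_factors(rng, 0.25, (n_cells, max_count))
        mask = np.arange(max_count)[None, :] < counts[:, None]
        droplet_signal = (per_droplet * mask).sum(axis=1)
    else:
        droplet_signal = np.zeros(n_cells)
    intensity = (config.flow_background + droplet_signal) * _lognormal_factors(
        rng, config.noise_cv, n_cells
    )
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "condition": condition,
            "intensity": intensity,
        }
    )


def gen_growth_curve(
    config: StudyConfig, timepoints_h: np.ndarray | None = None
) -> pd.DataFrame:
    """Cell-density time series under exponential growth.

    density(t) = growth_n0 * 2^(t / Td), with multiplicative lognormal
    counting noise of CV ``noise_cv``.  Columns:
    ``time_h, density_cells_per_ml``.
    """
    if timepoints_h is None:
        timepoints_h = np.asarray(config.decay_timepoints_h, dtype=float)
    else:
        timepoints_h = np.asarray(timepoints_h, dtype=float)
    if np.any(np.diff(timepoints_h) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = _rng(config, "growth")
    density = config.growth_n0 * np.exp2(timepoints_h / config.doubling_time_h)
    density = density * _lognormal_factors(rng, config.noise_cv, timepoints_h.size)
    return pd.DataFrame({"time_h": timepoints_h, "density_cells_per_ml": density})


def gen_decay_experiment(config: StudyConfig, replicate_offset: int = 0) -> pd.DataFrame:
    """Stored-signal decay series after oleate withdrawal.

    The true signal follows the kinetic model

        T(t) = B + (1 - B) * exp(-(mu + k) * t)

    with mu = ln2/Td, catabolic rate k = ``catabolic_rate_h`` and basal
    plateau B = ``basal_level`` (t = 0 signal normalized to 1); each of
    ``replicates`` replicates gets independent lognormal noise of CV
    ``noise_cv``.  Columns: ``time_h, replicate, signal``.
    """
    t = np.asarray(config.decay_timepoints_h, dtype=float)
    rate = config.mu + config.catabolic_rate_h
    b = config.basal_level
    true = b + (1.0 - b) * np.exp(-rate * t)
    rng = _rng(config, "decay", replicate_offset)
    rows = []
    for r in range(config.replicates):
        noise = _lognormal_factors(rng, config.noise_cv, t.size)
        rows.append(
            pd.DataFrame({"time_h": t, "replicate": r, "signal": true * noise})
        )
    return pd.concat(rows, ignore_index=True)


def _tag_catalog(config: StudyConfig) -> list[str]:
    """Distinct C:D class labels for the species catalog.

    Walks an acyl-carbon x double-bond grid (total carbons 44-58, even;
    0-11 double bonds) until ``n_tag_species`` labels are collected;
    the dominant classes are always included.
    """
    labels: list[str] = list(config.dominant_classes)
    carbons = range(44, 61, 2)
    for db in range(0, 12):
        for c in carbons:
            lab = f"{c}:{db}"
            if lab not in labels:
                labels.append(lab)
            if len(labels) >= config.n_tag_species:
                return labels[: config.n_tag_species]
    raise ValueError(f"cannot build a catalog of {config.n_tag_species} species")


def gen_lipidome(config: StudyConfig, condition: str = "fed") -> pd.DataFrame:
    """Shotgun-lipidomics TAG table with the spiked internal standard.

    Exactly ``n_tag_species`` species plus one TAG 17:0/17:0/17:0
    standard row.  Classes in ``dominant_classes`` carry their stated
    share of the total species intensity; the remainder is spread over
    the other species with seed-fixed random weights shared by both
    conditions, so fed/unfed differences reflect only the total TAG
    scale and measurement noise.  The fed total is ``flow_fold`` times
    the unfed total relative to the fixed standard spike.

    Columns: ``species_label, intensity, is_standard``.
    """
    _check_condition(condition)
    labels = _tag_catalog(config)
    n_dom = len([l for l in config.dominant_classes if l in labels])
    shares = np.empty(len(labels))
    for i, lab in enumerate(labels[:n_dom]):
        shares[i] = config.dominant_classes[lab]
    rest = 1.0 - shares[:n_dom].sum()
    if n_dom == 0:
        # no dominance structure: a fully symmetric catalog
        shares[:] = 1.0 / len(labels)
    else:
        # species composition is a property of the cells, not the run:
        # one condition-independent stream
        rng_comp = _rng(config, "lipidome", 0)
        w = rng_comp.gamma(0.8, size=len(labels) - n_dom)
        shares[n_dom:] = rest * w / w.sum()

    standard_intensity = 1.0e5
    total_unfed = 10.0 * standard_intensity
    total = total_unfed * (config.flow_fold if condition == "fed" else 1.0)
    rng_meas = _rng(config, "lipidome", 1 + _CONDITIONS.index(condition))
    raw = total * shares * _lognormal_factors(rng_meas, config.noise_cv, len(labels))

    df = pd.DataFrame(
        {
            "species_label": labels + ["TAG17:0/17:0/17:0"],
            "intensity": np.append(raw, standard_intensity),
            "is_standard": [0] * len(labels) + [1],
        }
    )
    return df


def gen_proteome_table(config: StudyConfig) -> pd.DataFrame:
    """Two-genotype label-free proteome table with one ablated protein.

    All proteins but one have a true WT/KO abundance ratio of 1; the
    ablated protein (id ``TFEA1``) keeps a residual KO noise-floor
    abundance of WT/``ablated_ratio``, so its computed ratio is finite.
    Reported abundances are means over ``replicates`` noisy replicate
    measurements (CV ``noise_cv`` each), as label-free pipelines report
    them.  10% of the non-ablated rows get peptide count 1 and are
    meant to be removed by the downstream >= 2-peptide filter.

    Columns: ``protein_id, abundance_wt, abundance_ko, peptides,
    confidence``.
    """
    rng = _rng(config, "proteome")
    n = config.n_proteins
    ids = [f"Tb927.{i // 100 + 1}.{1000 + i}" for i in range(n - 1)]
    ablated_pos = int(rng.integers(n))
    ids.insert(ablated_pos, ABLATED_PROTEIN_ID)

    base = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=n)

    def replicate_mean(true_values: np.ndarray) -> np.ndarray:
        reps = true_values[:, None] * _lognormal_factors(
            rng, config.noise_cv, (n, config.replicates)
        )
        return reps.mean(axis=1)

    true_ko = base.copy()
    true_ko[ablated_pos] = base[ablated_pos] / config.ablated_ratio
    abundance_wt = replicate_mean(base)
    abundance_ko = replicate_mean(true_ko)

    peptides = 2 + rng.poisson(6.0, size=n)
    n_single = max(1, round(0.1 * (n - 1)))
    non_ablated = np.delete(np.arange(n), ablated_pos)
    single_rows = rng.choice(non_ablated, size=n_single, replace=False)
    peptides[single_rows] = 1
    confidence = np.round(
        peptides * rng.lognormal(mean=math.log(40.0), sigma=0.3, size=n), 1
    )
    return pd.DataFrame(
        {
            "protein_id": ids,
            "abundance_wt": abundance_wt,
            "abundance_ko": abundance_ko,
            "peptides": peptides,
            "confidence": confidence,
        }
    )


# Specific activities (mU/mg protein), mean +/- SEM of n experiments,
# in whole-cell extracts (WCE) and glycosome-enriched fractions of WT
# and knockout cells grown with or without 10 mM glucose.  HADH is the
# NADPH-dependent 3-hydroxyacyl-CoA dehydrogenase activity; GPDH is the
# glycosomal marker.  Stored as a verbatim summary fixture (the raw
# replicates behind it are not available); no glycosomal -gluc
# measurements exist.
_ACTIVITY_FIXTURE = [
    ("WT", "WCE", "+gluc", "HADH", 6.62, 0.63, 5),
    ("WT", "WCE", "-gluc", "HADH", 5.22, 0.40, 5),
    ("KO", "WCE", "+gluc", "HADH", 6.04, 0.71, 5),
    ("KO", "WCE", "-gluc", "HADH", 5.00, 0.47, 5),
    ("WT", "glyco", "+gluc", "HADH", 11.76, 0.52, 6),
    ("KO", "glyco", "+gluc", "HADH", 9.12, 0.77, 6),
    ("WT", "WCE", "+gluc", "GPDH", 32.20, 3.48, 3),
    ("WT", "WCE", "-gluc", "GPDH", 34.92, 2.71, 3),
    ("KO", "WCE", "+gluc", "GPDH", 22.80, 2.45, 3),
    ("KO", "WCE", "-gluc", "GPDH", 35.40, 1.89, 3),
    ("WT", "glyco", "+gluc", "GPDH", 213.18, 4.12, 3),
    ("KO", "glyco", "+gluc", "GPDH", 208.22, 12.19, 3),
]


def gen_activity_table(config: StudyConfig | None = None) -> pd.DataFrame:
    """Enzyme specific-activity summary table (verbatim fixture).

    Columns: ``genotype, fraction, glucose, enzyme, mean_mU_per_mg,
    sem, n``.  Summary statistics are stored as given, not resampled,
    so the table is independent of the config's noise settings.
    """
    return pd.DataFrame(
        _ACTIVITY_FIXTURE,
        columns=[
            "genotype",
            "fraction",
            "glucose",
            "enzyme",
            "mean_mU_per_mg",
            "sem",
            "n",
        ],
    )


def gen_tlc_lane(config: StudyConfig, condition: str) -> pd.DataFrame:
    """TLC densitometry lanes: band areas per replicate.

    Bands sit at the standard R_F positions (phospholipids at the
    origin, DAG 0.08, FFA 0.29, TAG 0.50, steryl/other esters 0.90).
    The unfed TAG band area is the normalization anchor (mean 1.0); the
    fed TAG area is ``flow_fold`` times larger.  Replicate noise is
    multiplicative lognormal with CV ``noise_cv``.

    Columns: ``condition, replicate, rf, area``.
    """
    _check_condition(condition)
    rng = _rng(config, "tlc", _CONDITIONS.index(condition))
    rows = []
    for r in range(config.replicates):
        for band, (rf, base_area) in TLC_BANDS.items():
            area = base_area
            if band == "TAG" and condition == "fed":
                area *= config.flow_fold
            area *= _lognormal_factors(rng, config.noise_cv, ())
            rows.append((condition, r, rf, float(area)))
    return pd.DataFrame(rows, columns=["condition", "replicate", "rf", "area"])
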