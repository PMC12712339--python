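"""Synthetic multi-omics data with the statistical structure the pipeline
assumes, plus the planted ground truth needed for recovery tests.

The generator emulates the study design this package analyzes: four
endothelial cell types (two lymphatic, two blood-derived), sampled daily
over a ten-day course in triplicate, with day 2 representing active
proliferation and day 5 contact-inhibited quiescence. Intensities are
log2-normal around feature-specific baselines drawn Uniform(10, 25) in log2
units (the dynamic range of label-free proteomics / flow-injection
metabolomics data); planted effects are additive on the log2 scale.
Everything is driven by explicit seeds — no hidden global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import GeneSetCollection, OmicsMatrix, ReferenceMassList, SampleAnnotation

DEFAULT_CELL_TYPES = ("iLEC", "HDLEC", "HDBEC", "HUVEC")

#: hours at which supernatant is sampled after each medium exchange
SUPERNATANT_HOURS = (0.0, 2.0, 22.0, 24.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for all generators.

    Defaults mirror the emulated design: 4 cell types x days 1-10 x 3
    replicates; 10% of features carry a state (quiescence) effect and 10% a
    vascular-bed effect of 1.5 log2 units against replicate noise of
    0.25 log2 units; injection-order drift spans a 1.5x response change.
    """

    n_features: int = 1000
    n_cell_types: int = 4
    days: tuple[int, ...] = tuple(range(1, 11))
    n_replicates: int = 3
    frac_state_markers: float = 0.10
    frac_bed_markers: float = 0.10
    effect_size_log2: float = 1.5
    noise_sd_log2: float = 0.25
    drift_amplitude: float = 0.5
    seed: int = 0
    # supernatant series
    n_ions: int = 100
    rate_sd: float = 0.02             # SD of planted rates, h^-1
    max_abs_rate: float = 0.04        # keeps intensities positive at 24 h
    supernatant_noise_sd: float = 0.02  # relative to the t=0 intensity
    # phenotype
    growth_effect: float = 1.0        # treated growth rate / control (1 = none)
    migration_effect: float = 1.0     # treated closure / control
    phenotype_noise: float = 0.02
    # optional MNAR dropout: log2 intensities below this become missing
    dropout_threshold_log2: float | None = None
    baseline_log2_low: float = 10.0
    baseline_log2_high: float = 25.0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_cell_types < 1 or self.n_replicates < 1:
            raise ConfigurationError("counts must be >= 1")
        for name in ("frac_state_markers", "frac_bed_markers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.frac_state_markers + self.frac_bed_markers > 1.0:
            raise ConfigurationError("marker fractions sum to more than 1")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError("noise_sd_log2 must be > 0")
        if self.drift_amplitude < 0:
            raise ConfigurationError("drift_amplitude must be >= 0")
        if not self.days or any(d < 1 for d in self.days):
            raise ConfigurationError("days must be integers >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery assertions."""

    state_marker_direction: dict[str, int] = field(default_factory=dict)  # +1 = up in quiescence
    bed_marker_class: dict[str, str] = field(default_factory=dict)        # up in LEC or BEC
    supernatant_slopes: dict[str, float] = field(default_factory=dict)    # "ion|condition" -> h^-1
    drift_curve: dict[int, float] = field(default_factory=dict)           # acquisition idx -> factor

    @property
    def state_marker_ids(self) -> set[str]:
        return set(self.state_marker_direction)

    @property
    def bed_marker_ids(self) -> set[str]:
        return set(self.bed_marker_class)


def day_to_state(day: int) -> str:
    """Days <= 2 are proliferating, >= 5 quiescent, 3-4 transitional."""
    if day <= 2:
        return "proliferating"
    if day >= 5:
        return "quiescent"
    return "transitional"


def _cell_types(n: int) -> tuple[list[str], dict[str, str]]:
    if n == 4:
        names = list(DEFAULT_CELL_TYPES)
    else:
        names = [f"CT{i+1}" for i in range(n)]
    n_lec = max(1, (n + 1) // 2) if n > 1 else 1
    beds = {ct: ("LEC" if i < n_lec else "BEC") for i, ct in enumerate(names)}
    return names, beds


def gen_omics_matrix(
    cfg: SimulationConfig,
) -> tuple[OmicsMatrix, SampleAnnotation, PlantedTruth]:
    """Generate a feature x sample intensity matrix with planted effects.

    State markers shift by +/- effect_size_log2 in quiescent samples (half
    the effect in the transitional days 3-4); vascular-bed markers shift by
    the full effect in their bed's cell types across all days. Identical
    configs (including seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    features = [f"F{i+1:05d}" for i in range(cfg.n_features)]
    baselines = rng.uniform(cfg.baseline_log2_low, cfg.baseline_log2_high,
                            cfg.n_features)

    n_state = int(round(cfg.frac_state_markers * cfg.n_features))
    n_bed = int(round(cfg.frac_bed_markers * cfg.n_features))
    chosen = rng.permutation(cfg.n_features)
    state_idx = chosen[:n_state]
    bed_idx = chosen[n_state:n_state + n_bed]
    state_dir = rng.choice([-1, 1], size=n_state)
    bed_class = rng.choice(["LEC", "BEC"], size=n_bed)

    cell_types, bed_of = _cell_types(cfg.n_cell_types)
    meta_rows = []
    sample_ids = []
    for ct in cell_types:
        for day in cfg.days:
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{ct}_d{day:02d}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cell_type": ct,
                        "day": int(day),
                        "state": day_to_state(int(day)),
                        "vascular_bed": bed_of[ct],
                        "replicate": rep,
                        "treatment": None,
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["acquisition_index"] = rng.permutation(len(meta))

    state_weight = meta["state"].map(
        {"proliferating": 0.0, "transitional": 0.5, "quiescent": 1.0}
    ).to_numpy()
    is_lec = (meta["vascular_bed"] == "LEC").to_numpy()

    log2 = np.tile(baselines[:, None], (1, len(meta)))
    log2[state_idx] += (
        cfg.effect_size_log2 * state_dir[:, None] * state_weight[None, :]
    )
    bed_sign = np.where(bed_class == "LEC", 1.0, -1.0)
    log2[bed_idx] += (
        cfg.effect_size_log2 * bed_sign[:, None] * np.where(is_lec, 0.5, -0.5)[None, :]
    )
    log2 += rng.normal(0.0, cfg.noise_sd_log2, size=log2.shape)

    values = np.exp2(log2)
    if cfg.dropout_threshold_log2 is not None:
        values[log2 < cfg.dropout_threshold_log2] = np.nan
    matrix = OmicsMatrix(pd.DataFrame(values, index=features, columns=sample_ids))
    truth = PlantedTruth(
        state_marker_direction={features[i]: int(d)
                                for i, d in zip(state_idx, state_dir)},
        bed_marker_class={features[i]: str(c) for i, c in zip(bed_idx, bed_class)},
    )
    return matrix, SampleAnnotation(meta), truth


def gen_drifted_runs(
    cfg: SimulationConfig,
    base: OmicsMatrix,
    ann: SampleAnnotation,
    truth: PlantedTruth | None = None,
) -> OmicsMatrix:
    """Multiply each sample by a smooth monotone injection-order drift curve.

    The factor rises linearly from 1 at the first acquisition to
    1 + drift_amplitude at the last, so max/min = 1 + drift_amplitude;
    amplitude 0 returns the input unchanged.
    """
    if cfg.drift_amplitude < 0:
        raise ConfigurationError("drift_amplitude must be >= 0")
    order = ann.table.loc[base.sample_ids, "acquisition_index"].astype(int)
    n = len(order)
    span = max(n - 1, 1)
    factors = 1.0 + cfg.drift_amplitude * order.to_numpy() / span
    if truth is not None:
        truth.drift_curve = {int(i): float(f) for i, f in zip(order, factors)}
    drifted = base.data * factors
    return OmicsMatrix(drifted)


def gen_supernatant_series(
    cfg: SimulationConfig, days: tuple[int, ...] = (2, 5)
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Timed supernatant intensities with planted uptake/secretion slopes.

    For each ion x condition (cell type x day) a true rate r is drawn
    N(0, rate_sd) truncated to +/- max_abs_rate; each replicate series
    follows I(t) = I(0) * (1 + r t) + noise at t = 0, 2, 22, 24 h, with
    Gaussian noise of SD supernatant_noise_sd relative to I(0). r < 0
    encodes uptake, r > 0 secretion.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cell_types, _ = _cell_types(cfg.n_cell_types)
    truth = PlantedTruth()
    rows = []
    for i in range(cfg.n_ions):
        ion = f"ion_{i+1:04d}"
        for ct in cell_types:
            for day in days:
                cond = f"{ct}_D{day}"
                r = float(np.clip(rng.normal(0.0, cfg.rate_sd),
                                  -cfg.max_abs_rate, cfg.max_abs_rate))
                truth.supernatant_slopes[f"{ion}|{cond}"] = r
                for rep in range(1, cfg.n_replicates + 1):
                    i0 = float(np.exp2(rng.uniform(10.0, 20.0)))
                    for t in SUPERNATANT_HOURS:
                        noise = rng.normal(0.0, cfg.supernatant_noise_sd * i0)
                        rows.append(
                            {
                                "ion_id": ion,
                                "condition": cond,
                                "replicate": rep,
                                "hour": t,
                                "intensity": max(i0 * (1.0 + r * t) + noise, 0.0),
                            }
                        )
    return pd.DataFrame(rows), truth


def gen_phenotype_tables(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confluence curves and scratch widths for a control vs treated design.

    Growth follows a logistic curve with the treated growth rate scaled by
    ``growth_effect``; migration closes a fraction of an ~800 um scratch in
    12 h, scaled by ``migration_effect``. Multiplicative Gaussian noise of
    SD ``phenotype_noise`` is applied per measurement.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    hours = np.arange(0.0, 73.0, 6.0)
    cap, c0, g_ctrl = 1.0, 0.05, 0.08
    growth_rows = []
    for cond, g in (("control", g_ctrl), ("treated", g_ctrl * cfg.growth_effect)):
        for rep in range(1, cfg.n_replicates + 1):
            curve = cap / (1.0 + (cap - c0) / c0 * np.exp(-g * hours))
            curve = curve * (1.0 + rng.normal(0.0, cfg.phenotype_noise, hours.size))
            for h, c in zip(hours, curve):
                growth_rows.append(
                    {"condition": cond, "replicate": rep,
                     "hour": float(h), "confluence": max(float(c), 0.0)}
                )
    base_width, base_closed = 800.0, 400.0
    migration_rows = []
    for cond, eff in (("control", 1.0), ("treated", cfg.migration_effect)):
        for rep in range(1, cfg.n_replicates + 1):
            w0 = base_width * (1.0 + rng.normal(0.0, cfg.phenotype_noise))
            closed = base_closed * eff * (1.0 + rng.normal(0.0, cfg.phenotype_noise))
            migration_rows.append(
                {"condition": cond, "replicate": rep,
                 "width_0h_um": w0, "width_12h_um": w0 - closed}
            )
    return pd.DataFrame(growth_rows), pd.DataFrame(migration_rows)


def gen_gene_sets(
    feature_ids: list[str],
    truth: PlantedTruth,
    n_pathways: int,
    set_size: int,
    seed: int,
    n_signal: int = 2,
) -> GeneSetCollection:
    """Pathway sets: a few enriched for planted markers, the rest random.

    Signal pathway 1 draws from the planted state markers, signal pathway 2
    from the bed markers (topped up with random features if the marker pool
    is smaller than ``set_size``); remaining pathways are uniform draws.
    """
    if n_pathways < 0:
        raise ConfigurationError("n_pathways must be >= 0")
    if set_size > len(feature_ids):
        raise ConfigurationError("set_size exceeds the feature universe")
    rng = np.random.default_rng(seed)
    universe = np.asarray(feature_ids)
    pools = [sorted(truth.state_marker_ids), sorted(truth.bed_marker_ids)]
    names, members = {}, {}
    for i in range(n_pathways):
        pid = f"PW{i+1:03d}"
        if i < n_signal and i < len(pools) and pools[i]:
            pool = np.asarray(pools[i])
            take = rng.choice(pool, size=min(set_size, pool.size), replace=False)
            short = set_size - take.size
            if short > 0:
                rest = np.setdiff1d(universe, take)
                take = np.concatenate([take, rng.choice(rest, short, replace=False)])
            names[pid] = f"signal pathway {i+1}"
        else:
            take = rng.choice(universe, size=set_size, replace=False)
            names[pid] = f"random pathway {i+1}"
        members[pid] = frozenset(str(f) for f in take)
    return GeneSetCollection(names, members)


def gen_ion_table(
    cfg: SimulationConfig, n_compounds: int = 50
) -> tuple[pd.DataFrame, ReferenceMassList]:
    """Measured-ion list plus a reference mass list that annotates most of it.

    Compounds get masses Uniform(80, 900) Da; ions are their [M-H]- m/z
    values perturbed by N(0, 0.3 mDa) measurement error, plus a handful of
    unmatchable ions.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    masses = np.sort(rng.uniform(80.0, 900.0, n_compounds))
    ref = ReferenceMassList(
        pd.DataFrame(
            {
                "compound_id": [f"CPD{i+1:04d}" for i in range(n_compounds)],
                "name": [f"compound {i+1}" for i in range(n_compounds)],
                "monoisotopic_mass": masses,
            }
        )
    )
    proton = 1.007276
    mz = masses - proton + rng.normal(0.0, 0.0003, n_compounds)
    extra = rng.uniform(80.0, 900.0, max(n_compounds // 10, 1))
    all_mz = np.concatenate([mz, extra])
    ions = pd.DataFrame(
        {"ion_id": [f"ion_{i+1:04d}" for i in range(all_mz.size)], "mz": all_mz}
    )
    return ions, ref


def write_truth(truth: PlantedTruth, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "state_marker_direction": truth.state_marker_direction,
                "bed_marker_class": truth.bed_marker_class,
                "supernatant_slopes": truth.supernatant_slopes,
                "drift_curve": {str(k): v for k, v in truth.drift_curve.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def read_truth(path: str) -> PlantedTruth:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return PlantedTruth(
        state_marker_direction={k: int(v) for k, v in d["state_marker_direction"].items()},
        bed_marker_class=dict(d["bed_marker_class"]),
        supernatant_slopes={k: float(v) for k, v in d["supernatant_slopes"].items()},
        drift_curve={int(k): float(v) for k, v in d["drift_curve"].items()},
    )
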