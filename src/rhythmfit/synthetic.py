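"""Synthetic time-course panels with the study's sampling design.

Generates replicated damped-cosine series (0-48 h every 4 h, 6 replicates),
matching null (trend-only) series, and inverse-mapped Ct tables so the
quantification stage can be round-trip tested. Presets carry the published
per-cell-line parameter estimates; the metastatic-line BMAL1 series, for
which no fit was reported, defaults to its trend-only null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cosinor import DampedCosineParams, eval_damped_cosine
from .timecourse import TimeCourse

__all__ = [
    "GeneratorConfig",
    "PRESETS",
    "generate_timecourse",
    "generate_null",
    "generate_ct_table",
    "generate_panel",
]


@dataclass
class GeneratorConfig:
    """Design and noise description for one simulated series."""

    params: DampedCosineParams
    t_start: float = 0.0
    t_end: float = 48.0
    dt: float = 4.0
    n_replicates: int = 6
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    missing: tuple[tuple[int, int], ...] = ()
    seed: int | None = None
    label: tuple = ("sim", "gene")

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


def _apply_missing(values: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    if not config.missing:
        return values
    n_t, n_r = values.shape
    out = values.copy()
    for ti, ri in config.missing:
        if not (0 <= ti < n_t and 0 <= ri < n_r):
            raise ValueError(f"missing entry {(ti, ri)} outside the {values.shape} design")
        out[ti, ri] = np.nan
    if not np.isfinite(out).any(axis=1).all():
        empty = np.nonzero(~np.isfinite(out).any(axis=1))[0].tolist()
        raise ValueError(f"missing pattern empties entire time points {empty}")
    return out


def _noisy(truth: np.ndarray, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    shape = truth.shape
    if config.noise_sd == 0:
        return truth.copy()
    if config.noise_model == "gaussian":
        return truth + rng.normal(0.0, config.noise_sd, shape)
    # multiplicative, median-1 lognormal
    return truth * rng.lognormal(0.0, config.noise_sd, shape)


def generate_timecourse(config: GeneratorConfig) -> TimeCourse:
    """Replicated draws around the damped-cosine truth; seeded, reproducible."""
    rng = np.random.default_rng(config.seed)
    times = config.times
    truth = eval_damped_cosine(config.params, times)
    values = _noisy(np.tile(truth[:, None], (1, config.n_replicates)), config, rng)
    values = _apply_missing(values, config)
    return TimeCourse(config.label, times, values, {"truth": config.params})


def generate_null(config: GeneratorConfig) -> TimeCourse:
    """Arrhythmic series: linear trend ``b + m*t`` plus noise, no oscillation."""
    flat = replace(config.params, amplitude=0.0)
    return generate_timecourse(replace(config, params=flat))


def generate_ct_table(
    config: GeneratorConfig,
    reference_level: float = 20.0,
    efficiency_base: float = 2.0,
    calibrator_offset: float = 0.0,
    reference_gene: str = "GAPDH",
    ref_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Invert relative expression into a long-format Ct table.

    Reference-gene Ct sits at ``reference_level`` (optionally jittered);
    target Ct = ``reference_level + calibrator_offset - log_base(expression)``,
    so quantifying with a fixed calibrator dCt of ``calibrator_offset``
    reproduces the expression series exactly.
    """
    if efficiency_base <= 1:
        raise ValueError("efficiency_base must exceed 1")
    tc = generate_timecourse(config)
    expr = tc.values
    present = np.isfinite(expr)
    if np.any(expr[present] <= 0):
        raise ValueError("expression truth must be positive to map onto Ct values")
    cell_line, gene = (tc.label + ("sim", "gene"))[:2]
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    rows = []
    for ti, t in enumerate(tc.times):
        for ri in range(config.n_replicates):
            if not present[ti, ri]:
                continue
            # replicate ids stay unique across the two experiments so the
            # quantified matrix columns line up with the generated ones
            replicate = ri
            experiment = ri // 3
            ref_ct = reference_level + (
                rng.normal(0.0, ref_jitter_sd) if ref_jitter_sd > 0 else 0.0
            )
            tgt_ct = ref_ct + calibrator_offset - np.log(expr[ti, ri]) / np.log(
                efficiency_base
            )
            rows.append((cell_line, gene, t, replicate, experiment, tgt_ct))
            rows.append((cell_line, reference_gene, t, replicate, experiment, ref_ct))
    return pd.DataFrame(
        rows, columns=["cell_line", "gene", "time_h", "replicate", "experiment", "ct"]
    )


# ---------------------------------------------------------------------------
# presets: published per-(cell line, gene) damped-cosine estimates
# ---------------------------------------------------------------------------

def _p(a, lam, theta, tau, m, b) -> DampedCosineParams:
    return DampedCosineParams(
        amplitude=a, damping_rate=lam, phase=theta, period=tau, slope=m, intercept=b
    )


#: ``None`` marks the series reported as not-applicable (no acceptable fit);
#: it is simulated as a trend-only null sharing the cell line's PER2 trend.
PRESETS: dict[str, dict[str, DampedCosineParams | None]] = {
    "H16N2": {
        "BMAL1": _p(0.432, -0.015, 11.402, 26.546, 0.003, 0.910),
        "PER2": _p(0.309, -0.011, 26.952, 26.470, 0.018, 0.485),
    },
    "21PT": {
        "BMAL1": _p(0.085, -0.050, 6.001, 35.745, 0.023, 0.344),
        "PER2": _p(0.173, -0.028, 31.473, 30.621, 0.032, 0.254),
    },
    "21MT-1": {
        "BMAL1": None,
        "PER2": _p(0.208, -0.026, 27.033, 27.206, 0.006, 0.876),
    },
}

#: replicate 5 is absent at these time indices in the metastatic line,
#: giving 4 time points with n = 5 instead of 6
MT1_MISSING: tuple[tuple[int, int], ...] = ((2, 5), (5, 5), (8, 5), (11, 5))


def _preset_config(
    cell_line: str, gene: str, noise_sd: float, seed: int | None
) -> tuple[GeneratorConfig, bool]:
    params = PRESETS[cell_line][gene]
    is_null = params is None
    if is_null:
        trend = PRESETS[cell_line]["PER2"]
        assert trend is not None
        params = replace(trend, amplitude=0.0)
    missing = MT1_MISSING if cell_line == "21MT-1" else ()
    cfg = GeneratorConfig(
        params=params,
        noise_sd=noise_sd,
        missing=missing,
        seed=seed,
        label=(cell_line, gene),
    )
    return cfg, is_null


def generate_panel(
    preset: str,
    noise_sd: float = 0.05,
    seed: int | None = None,
    genes: Sequence[str] = ("BMAL1", "PER2"),
) -> dict[tuple, TimeCourse]:
    """Simulate a preset cell line (or ``"full"`` for all three) as a panel.

    Returns TimeCourses keyed by ``(cell_line, gene)``. Seeds are derived per
    series so a fixed ``seed`` reproduces the whole panel.
    """
    if preset == "full":
        cell_lines = list(PRESETS)
    elif preset in PRESETS:
        cell_lines = [preset]
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {list(PRESETS) + ['full']}")
    panel: dict[tuple, TimeCourse] = {}
    for i, cell_line in enumerate(cell_lines):
        for j, gene in enumerate(genes):
            sub_seed = None if seed is None else seed + 1009 * i + 101 * j
            cfg, is_null = _preset_config(cell_line, gene, noise_sd, sub_seed)
            tc = generate_null(cfg) if is_null else generate_timecourse(cfg)
            tc.meta["preset_null"] = is_null
            panel[(cell_line, gene)] = tc
    return panel
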