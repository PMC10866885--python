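"""Ground-truth benchmark protocols built on the synthetic generators.

These routines define the package's standard self-validation studies: FRAP
parameter recovery over a diffusion-coefficient grid (which also re-derives
the proportionality constant of the confocal Soumpasis relation),
dose-response model selection, oligomer classification against the
reported monomer/dimer control distributions, and kinetics recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frap import analyze_frap, classify_oligomer
from .kinetics import KineticsFitter
from .simulate import (
    CellPopConfig,
    FrapSimConfig,
    simulate_cell_population,
    simulate_frap,
    simulate_timecourse,
)
from .single_cell import (
    bin_population,
    fit_activation,
    measure_population,
    ttest_unpaired,
)

#: Reported monomer/dimer control diffusion coefficients (um^2/s): mean, sd.
MONOMER_CONTROL = (0.033, 0.013)
DIMER_CONTROL = (0.021, 0.005)


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def frap_parameter_recovery(
    d_values=(0.01, 0.02, 0.05),
    n_seeds: int = 10,
    base_seed: int = 0,
    **config_overrides,
) -> pd.DataFrame:
    """Full-pipeline D recovery over a diffusion grid.

    For each (D, seed): simulate an acquisition, correct and fit the
    recovery, estimate r_e from the rendered first post-bleach frame, and
    derive D_confocal. The returned table carries per-run t_half, r_e,
    D_est and the re-derived coefficient D_true * t_half / r_e^2.
    """
    seeds = _spawn_seeds(base_seed, len(d_values) * n_seeds)
    rows = []
    i = 0
    for d in d_values:
        for _ in range(n_seeds):
            cfg = FrapSimConfig(d=d, seed=seeds[i], **config_overrides)
            res = simulate_frap(cfg)
            out = analyze_frap(
                res.series,
                res.postbleach_frame,
                res.center_px,
                res.pixel_size,
                max_radius=4.0,
            )
            t_half = out["t_half_full"]
            rows.append(
                {
                    "d_true": d,
                    "seed": seeds[i],
                    "t_half": t_half,
                    "r_e": out["r_e"],
                    "d_est": out["d_confocal"],
                    "coefficient": d * t_half / out["r_e"] ** 2,
                    "rel_error": abs(out["d_confocal"] - d) / d,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def model_selection_benchmark(
    n_seeds: int = 20, base_seed: int = 0, **config_overrides
) -> pd.DataFrame:
    """Linear vs quadratic-threshold selection accuracy via the image pipeline."""
    seeds = _spawn_seeds(base_seed, 2 * n_seeds)
    rows = []
    for j, (law, want) in enumerate(
        [("linear", "linear"), ("quadratic_threshold", "quadratic")]
    ):
        for s in range(n_seeds):
            cfg = CellPopConfig(law=(law, None), seed=seeds[j * n_seeds + s],
                                **config_overrides)
            res = simulate_cell_population(cfg)
            cells = measure_population(
                res.expression, res.phospho, res.rois,
                res.background, res.background,
            )
            sel = fit_activation(bin_population(cells))
            rows.append({"law": law, "seed": cfg.seed, "selected": sel.model_,
                         "correct": sel.model_ == want})
    return pd.DataFrame(rows)


def oligomer_classification_benchmark(
    n_seeds: int = 20, n_cells: int = 20, base_seed: int = 0
) -> pd.DataFrame:
    """Label simulated monomer/dimer control populations per seed.

    Each seed draws one population per control (normal, using the reported control mean and
    sd); each population is classified against the two controls and the
    cross-group comparison must reach p < 0.05.
    """
    seeds = _spawn_seeds(base_seed, n_seeds)
    rows = []
    for s in seeds:
        rng = np.random.default_rng(s)
        mono = rng.normal(*MONOMER_CONTROL, size=n_cells)
        dim = rng.normal(*DIMER_CONTROL, size=n_cells)
        _, p_cross = ttest_unpaired(mono, dim)
        lab_mono = classify_oligomer(mono, mono, dim)["label"]
        lab_dim = classify_oligomer(dim, mono, dim)["label"]
        rows.append(
            {
                "seed": s,
                "p_cross": p_cross,
                "label_monomer_pop": lab_mono,
                "label_dimer_pop": lab_dim,
                "success": (
                    lab_mono == "monomer-like"
                    and lab_dim == "dimer-like"
                    and p_cross < 0.05
                ),
            }
        )
    return pd.DataFrame(rows)


def kinetics_recovery_benchmark(
    rise_slope: float = 0.17,
    t_half: float = 48.0,
    n_seeds: int = 10,
    base_seed: int = 0,
    window: float = 60.0,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Rise/decay recovery under the generator's default noise."""
    seeds = _spawn_seeds(base_seed, n_seeds)
    rows = []
    for s in seeds:
        course, truth = simulate_timecourse(
            rise_slope, t_half=t_half, window=window, noise_sd=noise_sd, seed=s
        )
        fit = KineticsFitter(window_end=window).fit(course)
        rows.append(
            {
                "seed": s,
                "rise_rate": fit.rise_rate_,
                "t_half": fit.t_half_decay_,
                "censored": fit.censored_,
                "true_rise": rise_slope,
                "true_t_half": truth["t_half"],
            }
        )
    return pd.DataFrame(rows)
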