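"""Packaged reference tables, readers/writers and the end-to-end pipeline.

The package ships the published medication-level summary tables as plain CSV:

* ``table1_heavy_craving`` - per-medication pooled heavy-drinking effect
  sizes (19 medications) and pooled cue-craving effect sizes (the 9
  medications tested in both paradigms);
* ``table2_abstinence`` - per-medication pooled abstinence effect sizes;
* ``table3_loo_heavy`` / ``table4_loo_abstinence`` - published observed vs
  leave-one-out predicted effect sizes for the 9 shared medications.

``run_pipeline`` drives pooling (for study-level input), both endpoint
regressions, the Monte Carlo power analysis and the leave-one-out
predictions, writing every artifact to an output directory.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .effect_sizes import effects_frame, read_studies_csv
from .loo_predict import loo_all, loo_frame
from .pooling import pool_by_medication
from .power_mc import PowerConfig, mc_power
from .synthetic import SyntheticConfig, regression_input_from_pools, simulate_dataset
from .wy_regression import RegressionInput, wy_fit

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "fixture_medication_effects",
    "fixture_regression_input",
    "run_pipeline",
]

logger = logging.getLogger("cuemeta")

FIXTURE_NAMES = (
    "table1_heavy_craving",
    "table2_abstinence",
    "table3_loo_heavy",
    "table4_loo_abstinence",
)

RCT_ENDPOINTS = ("heavy_drinking", "abstinence")

_EXPECTED_ROWS = {
    "table1_heavy_craving": 19,
    "table2_abstinence": 19,
    "table3_loo_heavy": 9,
    "table4_loo_abstinence": 9,
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table, validated against its known shape.

    Unicode minus signs survive transcription in some toolchains; they are
    normalized to ASCII hyphen-minus before numeric parsing.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("cuemeta.data") / f"{name}.csv"
    with ref.open("r", encoding="utf-8") as fh:
        text = fh.read().replace("−", "-")
    from io import StringIO

    frame = pd.read_csv(StringIO(text))
    if len(frame) != _EXPECTED_ROWS[name]:
        raise ValueError(
            f"fixture {name}: expected {_EXPECTED_ROWS[name]} rows, got {len(frame)}"
        )
    if frame["medication"].duplicated().any():
        raise ValueError(f"fixture {name}: duplicate medication rows")
    if name == "table1_heavy_craving" and frame["d_craving"].notna().sum() != 9:
        raise ValueError("fixture table1: expected 9 medications with craving values")
    return frame


def fixture_medication_effects() -> pd.DataFrame:
    """All fixture pooled effects in the ``medication_effects.csv`` schema.

    tau2 is not published at medication level and is reported as NaN here;
    it plays no role downstream of pooling.
    """
    t1 = load_fixture("table1_heavy_craving")
    t2 = load_fixture("table2_abstinence")
    parts = []
    craving = t1.dropna(subset=["d_craving"])
    parts.append(
        pd.DataFrame(
            {
                "medication": craving["medication"],
                "endpoint": "cue_craving",
                "d_pooled": craving["d_craving"].astype(float),
                "se_pooled": craving["se_craving"].astype(float),
                "k": craving["k_craving"].astype(int),
                "tau2": np.nan,
            }
        )
    )
    parts.append(
        pd.DataFrame(
            {
                "medication": t1["medication"],
                "endpoint": "heavy_drinking",
                "d_pooled": t1["d_heavy"].astype(float),
                "se_pooled": t1["se_heavy"].astype(float),
                "k": t1["k_heavy"].astype(int),
                "tau2": np.nan,
            }
        )
    )
    parts.append(
        pd.DataFrame(
            {
                "medication": t2["medication"],
                "endpoint": "abstinence",
                "d_pooled": t2["d"].astype(float),
                "se_pooled": t2["se"].astype(float),
                "k": t2["k"].astype(int),
                "tau2": np.nan,
            }
        )
    )
    return pd.concat(parts, ignore_index=True)


def fixture_regression_input(endpoint: str = "heavy_drinking") -> RegressionInput:
    """The 9-medication regression dataset for one clinical endpoint."""
    if endpoint not in RCT_ENDPOINTS:
        raise ValueError(f"endpoint must be one of {RCT_ENDPOINTS}")
    pooled = fixture_medication_effects()
    inp = regression_input_from_pools(pooled, endpoint=endpoint)
    if inp.n_points != 9:
        raise ValueError(
            f"fixture join for {endpoint} has {inp.n_points} medications, expected 9"
        )
    return inp


def _fit_row(fit) -> dict:
    return {
        "endpoint": fit.endpoint,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "se_slope": fit.se_slope,
        "se_intercept": fit.se_intercept,
        "se_slope_raw": fit.se_slope_raw,
        "z": fit.z,
        "p_one_sided": fit.p_one_sided,
        "alpha": fit.alpha,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "selection": fit.selection,
    }


def run_pipeline(
    source: str = "fixtures",
    out_dir: Optional[str | Path] = None,
    *,
    studies_csv: Optional[str | Path] = None,
    synthetic_config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
    power_reps: int = 10_000,
    loo_draws: int = 10_000,
) -> dict:
    """Run pooling, both endpoint regressions, power and LOO prediction.

    ``source`` is ``"fixtures"`` (packaged published tables), ``"csv"``
    (study-level arm summaries via ``studies_csv``) or ``"synthetic"``.
    Returns a results bundle dict; writes CSV/JSON artifacts when ``out_dir``
    is given. Medications present in only one paradigm are retained in the
    pooled output but excluded from the regressions (inner-join semantics).
    """
    rng_seed = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seed.spawn(4)]
    results: dict = {"source": source, "seed": seed}

    if source == "fixtures":
        pooled = fixture_medication_effects()
    elif source == "csv":
        if studies_csv is None:
            raise ValueError("source='csv' requires studies_csv")
        records = read_studies_csv(studies_csv)
        effects = effects_frame(records)
        results["effects"] = effects
        pooled = pool_by_medication(effects)
    elif source == "synthetic":
        config = synthetic_config or SyntheticConfig(seed=sub_seeds[0])
        records, truth = simulate_dataset(config)
        results["truth"] = truth
        effects = effects_frame(records)
        results["effects"] = effects
        pooled = pool_by_medication(effects)
    else:
        raise ValueError(f"unknown source {source!r}")
    results["medication_effects"] = pooled

    fit_rows, power_rows, loo_frames = [], {}, {}
    for i, endpoint in enumerate(RCT_ENDPOINTS):
        try:
            inp = (
                fixture_regression_input(endpoint)
                if source == "fixtures"
                else regression_input_from_pools(pooled, endpoint=endpoint)
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", endpoint, exc)
            continue
        dropped = sorted(
            set(pooled.loc[pooled["endpoint"] == endpoint, "medication"])
            - set(inp.labels)
        )
        if dropped:
            logger.info(
                "%s: excluded from regression (no cue-craving estimate): %s",
                endpoint, ", ".join(dropped),
            )
        fit = wy_fit(inp, select="positive")
        fit_rows.append(_fit_row(fit))
        power = mc_power(
            inp,
            PowerConfig(n_reps=power_reps, seed=sub_seeds[1] + i,
                        slope=fit.slope, intercept=fit.intercept),
        )
        power_rows[endpoint] = power.to_dict()
        dists = loo_all(inp, draws=loo_draws, seed=sub_seeds[2] + i, full_fit=fit)
        loo_frames[endpoint] = loo_frame(dists)

    results["regressions"] = pd.DataFrame(fit_rows)
    results["power"] = power_rows
    results["loo"] = loo_frames

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pooled.to_csv(out / "medication_effects.csv", index=False)
        if "effects" in results:
            results["effects"].to_csv(out / "effects.csv", index=False)
        if "truth" in results:
            results["truth"].to_csv(out / "truth.csv", index=False)
        for row in fit_rows:
            pd.DataFrame([row]).to_csv(
                out / f"regression_{row['endpoint']}.csv", index=False
            )
        for endpoint, frame in loo_frames.items():
            frame.to_csv(out / f"loo_{endpoint}.csv", index=False)
        with open(out / "power.json", "w") as fh:
            json.dump(power_rows, fh, indent=2)
        with open(out / "run.json", "w") as fh:
            json.dump({"source": source, "seed": seed,
                       "power_reps": power_reps, "loo_draws": loo_draws}, fh, indent=2)
    return results


def plot_regression(inp: RegressionInput, fit, path) -> None:
    """Scatter of the medication effects with the fitted line.

    Dot area is proportional to the total precision 1/(sx^2 + sy^2).
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    area = 1.0 / (inp.sx**2 + inp.sy**2)
    area = 200 * area / area.max()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(inp.x, inp.y, s=area, alpha=0.7)
    for xi, yi, lab in zip(inp.x, inp.y, inp.labels):
        ax.annotate(lab, (xi, yi), fontsize=7, xytext=(2, 2),
                    textcoords="offset points")
    xs = np.linspace(inp.x.min(), inp.x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-",
            label=f"slope {fit.slope:.3f} (SE {fit.se_slope:.3f})")
    ax.set_xlabel("cue-craving effect size (d)")
    ax.set_ylabel(f"{inp.endpoint or 'clinical'} effect size (d)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
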