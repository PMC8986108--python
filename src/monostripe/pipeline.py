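"""Reproducible analysis workflows tying the model and image layers together.

Each run* function is a plain library entry point used both by the CLI
and by scripts; outputs are pandas DataFrames or plain dicts that carry
the seed and a short hash of the configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources

import numpy as np
import pandas as pd

from . import morphometrics, stoichiometry, synthetic
from .energetics import BondParameters
from .stripes import (
    EXACT_WIDTH_PREFACTOR,
    ROUNDED_WIDTH_PREFACTOR,
    bond_number_from_width,
    branch_diagram,
    limiting_stripe_width,
)

__all__ = [
    "config_hash",
    "load_width_fixture",
    "run_branch_diagram",
    "run_width_to_bond",
    "run_stoichiometry",
    "run_recovery_experiment",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def load_width_fixture() -> pd.DataFrame:
    """Packaged table of measured equilibrium stripe widths.

    Each row records one reported width (um +/- sd) with its figure
    panel, lipid system, DPPC chirality, spreading ratio b, DChol
    fraction and conditions, so no number is orphaned.
    """
    with resources.files("monostripe.data").joinpath("stripe_widths.csv").open() as fh:
        return pd.read_csv(fh)


def run_branch_diagram(A_bar_max: float = 20.0, n: int = 200) -> pd.DataFrame:
    """Square + rectangular branch table (see :func:`~monostripe.stripes.branch_diagram`)."""
    return branch_diagram(A_bar_max=A_bar_max, n=n)


def run_width_to_bond(
    widths: pd.DataFrame | None = None,
    delta_nm: float = 1.0,
    prefactor: float = ROUNDED_WIDTH_PREFACTOR,
) -> pd.DataFrame:
    """Convert a stripe-width table to inverse Bond numbers.

    Adds ``lambda_over_mu2`` (requested prefactor, conventionally 5.5)
    and ``lambda_over_mu2_exact`` (exact 2e prefactor).  Rows whose
    width does not exceed prefactor*delta are flagged, not fatal.
    Widths in um, delta in nm.
    """
    df = (widths if widths is not None else load_width_fixture()).copy()
    if "delta_nm" not in df.columns:
        df["delta_nm"] = delta_nm
    df["delta_nm"] = df["delta_nm"].fillna(delta_nm)
    vals, exact, flags = [], [], []
    for _, row in df.iterrows():
        w_nm = 1000.0 * float(row["width_um"])
        d = float(row["delta_nm"])
        try:
            vals.append(bond_number_from_width(w_nm, d, prefactor=prefactor))
            exact.append(bond_number_from_width(w_nm, d, prefactor=EXACT_WIDTH_PREFACTOR))
            flags.append("")
        except ValueError:
            vals.append(np.nan)
            exact.append(np.nan)
            flags.append("below_resolution_floor")
    df["lambda_over_mu2"] = vals
    df["lambda_over_mu2_exact"] = exact
    df["flag"] = flags
    return df


def run_stoichiometry(
    phi_table: pd.DataFrame,
    j: float = 0.0,
    weighted: bool = False,
    candidates: tuple[int, ...] = (1, 2, 3),
    b_grid: np.ndarray | None = None,
) -> tuple[stoichiometry.StoichiometryFit, pd.DataFrame]:
    """Fit the crystal stoichiometry and emit phi(b) curves for each candidate.

    ``phi_table`` needs columns (b, phi[, sd]).  Returns the fit and a
    DataFrame of predicted curves on ``b_grid`` for plotting.
    """
    obs = [
        stoichiometry.AreaFractionObservation(
            b=float(r["b"]), phi=float(r["phi"]), sd=float(r.get("sd", 0.0) or 0.0)
        )
        for _, r in phi_table.iterrows()
    ]
    fit = stoichiometry.fit_stoichiometry(
        obs, j=j, candidates=candidates, weighted=weighted
    )
    if b_grid is None:
        b_grid = np.linspace(max(candidates), max(10.0, phi_table["b"].max()), 50)
    curves = {"b": b_grid}
    for n in candidates:
        if n in fit.excluded:
            continue
        curves[f"phi_n{n}"] = stoichiometry.area_fraction_curve(b_grid, n=n, j=j)
    return fit, pd.DataFrame(curves)


def run_recovery_experiment(
    true_values: tuple[float, ...] = (5.0, 6.0, 7.0),
    delta_nm: float = 1.0,
    pixel_size: float = 0.2,
    image_size: int = 512,
    n_images: int = 3,
    seed: int = 0,
) -> dict:
    """End-to-end inverse Bond number recovery from synthetic stripe images.

    For each true lambda/mu^2, stripe images are generated at the
    limiting width 5.5 * delta * e^(lambda/mu^2) (the same rounded
    prefactor used by the inversion, so the chain probes measurement
    error, not the documented 5.5-vs-2e rounding), measured with the
    medial-axis estimator, and inverted back.  Reports per-value means
    and the overall bias and RMSE of the recovered ratio.
    """
    rng = np.random.default_rng(seed)
    cfg = {
        "true_values": list(true_values),
        "delta_nm": delta_nm,
        "pixel_size": pixel_size,
        "image_size": image_size,
        "n_images": n_images,
        "seed": seed,
    }
    per_value = []
    errors = []
    for c in true_values:
        w_um = ROUNDED_WIDTH_PREFACTOR * delta_nm * math.exp(c) / 1000.0
        period = 2.5 * w_um
        recovered = []
        for _ in range(n_images):
            img = synthetic.generate_stripes(
                width=w_um,
                period=period,
                orientation=float(rng.uniform(0.0, 180.0)),
                image_size=image_size,
                pixel_size=pixel_size,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            est = morphometrics.stripe_width_medial(img)
            rec = bond_number_from_width(
                1000.0 * est.mean_width, delta_nm, prefactor=ROUNDED_WIDTH_PREFACTOR
            )
            recovered.append(rec)
            errors.append(rec - c)
        per_value.append(
            {
                "true": c,
                "width_um": w_um,
                "recovered_mean": float(np.mean(recovered)),
                "recovered_sd": float(np.std(recovered, ddof=1))
                if len(recovered) > 1
                else 0.0,
            }
        )
    errors = np.asarray(errors)
    return {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "per_value": per_value,
        "bias": float(errors.mean()),
        "rmse": float(np.sqrt((errors**2).mean())),
        "limiting_width_check_um": {
            str(c): limiting_stripe_width(BondParameters(c, delta_nm)) / 1000.0
            for c in true_values
        },
    }
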