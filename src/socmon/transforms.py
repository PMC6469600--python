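"""Variable transformations used before trend modelling and ordination.

Three transforms cover the variable types of a soil-monitoring covariate
table: natural log for strictly positive, right-skewed quantities (SOC,
altitude); log with an additive offset for non-negative quantities with
genuine zeros (farmyard-manure inputs), where the offset

    c = median(x) / (median(x) / q0.25(x)) ** 2.9

estimates the 0.025 quantile of the positive part of the distribution
(exact for a lognormal, where it reduces to exp(mu - 1.956 sigma)); and the
arcsine-square-root transform for percentages (clay, silt, crop-category
proportions), applied to proportions in [0, 1] and returning radians.

The transformed covariate matrix is the hand-off to any external robust-PCA
or ordination tool; :func:`export_transformed_matrix` writes it with a
sidecar file recording exactly which transform (and offset) produced each
column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TransformSpec",
    "compute_offset",
    "apply_transform",
    "transform_table",
    "export_transformed_matrix",
]

OFFSET_EXPONENT = 2.9  # fixed constant of the offset formula, not tunable


@dataclass(frozen=True)
class TransformSpec:
    """How one variable is transformed.

    kind: one of ``log``, ``log_offset``, ``arcsine_sqrt``, ``none``.
    offset_c: additive offset, populated for ``log_offset`` only.
    percent: for ``arcsine_sqrt``, divide input by 100 first.
    quantile_method: quantile estimator used when the offset was computed
      (recorded for reproducibility).
    """

    kind: str
    offset_c: float | None = None
    percent: bool = False
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in {"log", "log_offset", "arcsine_sqrt", "none"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "log_offset":
            if self.offset_c is None or not (self.offset_c > 0):
                raise ValueError("log_offset requires offset_c > 0")


def compute_offset(x, quantile_method: str = "linear") -> float:
    """Offset c = median(x) / (median(x)/q0.25(x))^2.9 for a log-offset transform.

    Quantiles use linear interpolation between order statistics by default;
    the estimator is recorded in the resulting :class:`TransformSpec` so the
    transform is reproducible.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot compute an offset from an empty vector")
    med = float(np.quantile(x, 0.5, method=quantile_method))
    q25 = float(np.quantile(x, 0.25, method=quantile_method))
    if med <= 0:
        raise ValueError("offset undefined: median of the input is not positive")
    if q25 <= 0:
        raise ValueError("offset undefined: 0.25 quantile of the input is not positive")
    return med / (med / q25) ** OFFSET_EXPONENT


def log_offset_spec(x, quantile_method: str = "linear") -> TransformSpec:
    """Convenience: compute the offset for ``x`` and wrap it in a spec."""
    return TransformSpec(
        "log_offset", offset_c=compute_offset(x, quantile_method),
        quantile_method=quantile_method,
    )


def apply_transform(x, spec: TransformSpec) -> np.ndarray:
    """Apply one transform elementwise; domain violations name the element."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "none":
        return x.copy()
    if spec.kind == "log":
        bad = np.flatnonzero(~(x > 0))
        if bad.size:
            raise ValueError(f"log transform requires values > 0; element(s) {bad.tolist()}")
        return np.log(x)
    if spec.kind == "log_offset":
        shifted = x + spec.offset_c
        bad = np.flatnonzero(~(shifted > 0))
        if bad.size:
            raise ValueError(
                f"log_offset transform requires x + c > 0; element(s) {bad.tolist()}"
            )
        return np.log(shifted)
    # arcsine_sqrt
    p = x / 100.0 if spec.percent else x
    bad = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    if bad.size:
        raise ValueError(
            f"arcsine_sqrt requires proportions in [0, 1]; element(s) {bad.tolist()}"
        )
    return np.arcsin(np.sqrt(p))


def transform_table(df: pd.DataFrame, specs: Mapping[str, TransformSpec]) -> pd.DataFrame:
    """Transform the named columns; columns without a spec are dropped."""
    out = {}
    for col, spec in specs.items():
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in table")
        vals = df[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        res = np.full(vals.shape, np.nan)
        res[mask] = apply_transform(vals[mask], spec)
        out[col] = res
    return pd.DataFrame(out, index=df.index)


def export_transformed_matrix(
    df: pd.DataFrame,
    specs: Mapping[str, TransformSpec],
    path: str | Path,
) -> Path:
    """Write the transformed matrix as CSV plus a JSON sidecar of the specs.

    Returns the sidecar path (``<path>.transforms.json``).
    """
    path = Path(path)
    transform_table(df, specs).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".transforms.json")
    sidecar.write_text(
        json.dumps({col: asdict(spec) for col, spec in specs.items()}, indent=2)
    )
    return sidecar
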