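"""Post-processing of QSAR effect-concentration predictions.

The VEGA IRFMN acute EC50 models (algae, Daphnia magna, fish) report
toxicity as −log10(mmol/L) plus a raw, a-dimensional model output.  The
deployed model version mis-estimated molecular weights, so the published
−log values cannot be trusted for the algae and fish models; instead the
a-dimensional value is back-transformed through a box-cox-type power
function:

    EC50_algae [mmol/L] = (a · 0.07 + 1) ** (1.0 / 0.07)
    EC50_fish  [mmol/L] = (a · 0.11 + 1) ** (1.0 / 0.07)

The fish exponent 1.0/0.07 is as printed; box-cox symmetry would suggest
1.0/0.11, and that alternative reading is selectable via ``fish_exponent``.
No correction applies to the Daphnia model: its −log values are
back-transformed directly.  Values outside the transformation's domain
(base ≤ 0) become missing with a warning, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ALGAE_LAMBDA",
    "FISH_LAMBDA",
    "DEFAULT_FISH_EXPONENT",
    "MODELS",
    "VegaPrediction",
    "correct_algae",
    "correct_fish",
    "daphnia_from_neglog",
    "mmol_to_mg",
    "parse_qsar_outputs",
]

ALGAE_LAMBDA = 0.07
FISH_LAMBDA = 0.11
#: exponent of the fish back-transformation as printed in the source workflow
DEFAULT_FISH_EXPONENT = 1.0 / 0.07

MODELS = ("algae_EC50", "daphnia_EC50", "fish_EC50")


@dataclass
class VegaPrediction:
    """One model × compound prediction with derived EC50s.

    ``neglog_mmol`` is the model's reported −log10(mmol/L) value,
    ``a_dimensional`` the raw output, ``ad_assessment`` the
    applicability-domain text passed through verbatim.  ``ec50_mmol`` and
    ``ec50_mg`` are filled by the correction step.
    """

    chemical_id: str
    model: str
    neglog_mmol: float = float("nan")
    a_dimensional: float = float("nan")
    ad_assessment: str = ""
    ec50_mmol: float = float("nan")
    ec50_mg: float = float("nan")

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")


def _boxcox_inverse(a: float, lam: float, exponent: float) -> float:
    if a is None or not np.isfinite(a):
        return float("nan")
    base = a * lam + 1.0
    if base <= 0:
        warnings.warn(
            f"a-dimensional value {a} gives non-positive box-cox base {base}; "
            "prediction set to missing",
            stacklevel=3,
        )
        return float("nan")
    return float(base ** exponent)


def correct_algae(a: float) -> float:
    """EC50 in mmol/L from the algae model's a-dimensional output:
    ``(a·0.07 + 1) ** (1/0.07)``."""
    return _boxcox_inverse(a, ALGAE_LAMBDA, 1.0 / ALGAE_LAMBDA)


def correct_fish(a: float, exponent: float = DEFAULT_FISH_EXPONENT) -> float:
    """EC50 in mmol/L from the fish model's a-dimensional output:
    ``(a·0.11 + 1) ** exponent`` with exponent 1/0.07 by default.

    Pass ``exponent=1.0/0.11`` for the symmetric box-cox reading.
    """
    return _boxcox_inverse(a, FISH_LAMBDA, exponent)


def daphnia_from_neglog(pred: float) -> float:
    """EC50 in mmol/L from a −log10(mmol/L) prediction: ``10**(−pred)``."""
    if pred is None or not np.isfinite(pred):
        return float("nan")
    return float(10.0 ** (-pred))


def mmol_to_mg(ec: float, mw: float) -> float:
    """mmol/L → mg/L: ``ec × mw`` with ``mw`` in g/mol."""
    if mw is None or not np.isfinite(mw):
        return float("nan")
    if ec is None or np.isnan(ec):
        return float("nan")
    if ec <= 0 or mw <= 0:
        raise ValueError(f"ec and mw must be > 0, got ec={ec}, mw={mw}")
    return float(ec * mw)


def correct_prediction(
    pred: VegaPrediction,
    mw: float | None = None,
    fish_exponent: float = DEFAULT_FISH_EXPONENT,
) -> VegaPrediction:
    """Fill ``ec50_mmol`` (and ``ec50_mg`` when mw is given) in place."""
    if pred.model == "algae_EC50":
        pred.ec50_mmol = correct_algae(pred.a_dimensional)
    elif pred.model == "fish_EC50":
        pred.ec50_mmol = correct_fish(pred.a_dimensional, exponent=fish_exponent)
    else:
        pred.ec50_mmol = daphnia_from_neglog(pred.neglog_mmol)
    if mw is not None and np.isfinite(pred.ec50_mmol):
        pred.ec50_mg = mmol_to_mg(pred.ec50_mmol, mw)
    return pred


DEFAULT_COLUMNS = {
    "id": "Id",
    "neglog": "Prediction",
    "a_dimensional": "A_dimensional",
    "ad": "AD_assessment",
}


def parse_qsar_outputs(
    paths: dict[str, object],
    columns: dict[str, str] | None = None,
    sep: str = ",",
) -> list[VegaPrediction]:
    """Read per-model VEGA export files into predictions.

    ``paths`` maps a model name (``algae_EC50``, ``daphnia_EC50``,
    ``fish_EC50``) to its delimited export.  A compound absent from one
    model's output simply has no prediction for that model; a compound
    duplicated within one file is ambiguous and raises.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    preds: list[VegaPrediction] = []
    for model, path in paths.items():
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
        df = pd.read_csv(path, sep=sep, dtype={cols["id"]: str})
        if df[cols["id"]].duplicated().any():
            dup = df[cols["id"]][df[cols["id"]].duplicated()].iloc[0]
            raise ValueError(f"compound {dup!r} duplicated in {model} output")
        for _, row in df.iterrows():
            preds.append(
                VegaPrediction(
                    chemical_id=str(row[cols["id"]]),
                    model=model,
                    neglog_mmol=float(pd.to_numeric(row.get(cols["neglog"]), errors="coerce"))
                    if cols["neglog"] in df.columns else float("nan"),
                    a_dimensional=float(pd.to_numeric(row.get(cols["a_dimensional"]), errors="coerce"))
                    if cols["a_dimensional"] in df.columns else float("nan"),
                    ad_assessment=str(row[cols["ad"]])
                    if cols["ad"] in df.columns and pd.notna(row.get(cols["ad"])) else "",
                )
            )
    return preds
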