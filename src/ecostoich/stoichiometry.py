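"""Ecoenzymatic stoichiometry and the enzyme vector model.

Soil extracellular enzymes index microbial investment in carbon, nitrogen
and phosphorus acquisition: BG (beta-1,4-glucosidase, C), NAG + LAP
(beta-N-acetylglucosaminidase and leucine aminopeptidase, N; always summed)
and ALP (alkaline phosphatase, P). The stoichiometric ratios are ratios of
natural logs of activities,

    E_C:N = ln BG / ln(NAG + LAP)
    E_C:P = ln BG / ln ALP
    E_N:P = ln(NAG + LAP) / ln ALP

so activities must exceed 1 in working units (nmol g-1 h-1) for the logs
to be strictly positive. The vector model plots x = E_C:P against
y = E_C:N: vector length sqrt(x^2 + y^2) indexes relative C limitation,
and the vector angle atan(y/x), in degrees, indicates N limitation below
45 degrees and P limitation above (ALP dominance over NAG + LAP pushes the
angle above 45). A second, quadrant-based classification uses the raw
activity ratios (NAG+LAP)/ALP and BG/(NAG+LAP) against baselines of 1.

Note these ratios of logs are *not* invariant to a common rescaling of all
activities; the working unit is part of the definition (a configurable
``rescale`` factor is applied, loudly, before the logs when input units
differ).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BOUNDARY_TOL = 1e-9

#: Quadrant -> limitation label, keyed by (q_x > 1, q_y > 1) with
#: q_x = (NAG+LAP)/ALP and q_y = BG/(NAG+LAP). q_y > 1 reads as C-acquisition
#: dominant over N, q_x < 1 as P-acquisition dominant over N.
DEFAULT_QUADRANT_LABELS = {
    (False, True): "C & P limitation",
    (False, False): "P limitation",
    (True, False): "N limitation",
    (True, True): "N & P limitation",
}

STOICH_QUANTITIES = ["ECN", "ECP", "ENP", "vector_length", "vector_angle"]


class ActivityDomainError(ValueError):
    """Enzyme activity outside the domain of the ln-ratio definitions."""


def _check_positive_log(value, name: str):
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ActivityDomainError(f"{name}: activity non-positive")
    if np.any(value <= 1):
        raise ActivityDomainError(
            f"{name}: log non-positive (activity must exceed 1 working unit)"
        )
    return value


def ln_ratios(BG, NAG, LAP, ALP, convention: str = "ratio_of_logs"):
    """Compute (E_C:N, E_C:P, E_N:P) from the four enzyme activities.

    Scalar or array inputs. ``convention`` selects the canonical
    ratio-of-logs definition or the alternative log-of-ratio reading
    (ln(BG/ALP) etc.); the default is the one the study's tabulated ratios
    follow.
    """
    if convention not in ("ratio_of_logs", "log_of_ratio"):
        raise ValueError(f"unknown ratio convention {convention!r}")
    NL = np.asarray(NAG, dtype=float) + np.asarray(LAP, dtype=float)
    bg = _check_positive_log(BG, "BG")
    nl = _check_positive_log(NL, "NAG+LAP")
    alp = _check_positive_log(ALP, "ALP")
    if convention == "log_of_ratio":
        ecn = np.log(bg / nl)
        ecp = np.log(bg / alp)
        enp = np.log(nl / alp)
    else:
        ecn = np.log(bg) / np.log(nl)
        ecp = np.log(bg) / np.log(alp)
        enp = np.log(nl) / np.log(alp)
    if np.ndim(BG) == 0 and np.ndim(NAG) == 0:
        return float(ecn), float(ecp), float(enp)
    return ecn, ecp, enp


def vector_metrics(x, y):
    """Vector length and angle (degrees) from x = E_C:P, y = E_C:N.

    length = sqrt(x^2 + y^2); angle = atan(y/x) in degrees, in (0, 90) for
    positive coordinates. Requires x > 0 and y > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ActivityDomainError("vector coordinates must be strictly positive")
    length = np.hypot(x, y)
    angle = np.degrees(np.arctan2(y, x))
    if x.ndim == 0 and y.ndim == 0:
        return float(length), float(angle)
    return length, angle


def classify_angle(angle: float, tol: float = BOUNDARY_TOL) -> str:
    """'N' below 45 degrees, 'P' above, 'boundary' at 45 (within tol)."""
    if not (0.0 <= angle <= 90.0):
        raise ValueError(f"angle out of range [0, 90]: {angle}")
    if abs(angle - 45.0) <= tol:
        return "boundary"
    return "P" if angle > 45.0 else "N"


def quadrant_classify(BG, NAG, LAP, ALP, labels=None, tol: float = BOUNDARY_TOL) -> str:
    """Limitation group from raw activity ratios against baselines of 1."""
    for name, v in (("BG", BG), ("NAG", NAG), ("LAP", LAP), ("ALP", ALP)):
        if v <= 0:
            raise ActivityDomainError(f"{name}: activity non-positive")
    labels = DEFAULT_QUADRANT_LABELS if labels is None else labels
    q_x = (NAG + LAP) / ALP
    q_y = BG / (NAG + LAP)
    if abs(q_x - 1.0) <= tol or abs(q_y - 1.0) <= tol:
        return "boundary"
    return labels[(q_x > 1.0, q_y > 1.0)]


@dataclass
class StoichOptions:
    convention: str = "ratio_of_logs"
    rescale: float = 1.0
    tol: float = BOUNDARY_TOL


def compute_stoichiometry(
    samples: pd.DataFrame,
    convention: str = "ratio_of_logs",
    rescale: float = 1.0,
) -> pd.DataFrame:
    """Per-sample stoichiometric ratios, vector metrics and classifications.

    ``samples`` needs columns BG, NAG, LAP, ALP plus any identifier columns
    (zone, depth_layer, plot_id are carried through when present). If the
    table has a ``fraction`` column only the enzyme-fraction rows are used.
    ``rescale`` multiplies all four activities before the logs, for inputs
    recorded in a different working unit.
    """
    df = samples
    if "fraction" in df.columns:
        df = df[df["fraction"] == "enzyme"]
    if rescale != 1.0:
        logger.warning("rescaling all enzyme activities by factor %g before logs",
                       rescale)
    act = {e: df[e].to_numpy(dtype=float) * rescale for e in ("BG", "NAG", "LAP", "ALP")}
    ecn, ecp, enp = ln_ratios(act["BG"], act["NAG"], act["LAP"], act["ALP"],
                              convention=convention)
    length, angle = vector_metrics(ecp, ecn)
    keys = [c for c in ("zone", "depth_layer", "plot_id") if c in df.columns]
    out = df[keys].copy() if keys else pd.DataFrame(index=df.index)
    out["ECN"] = ecn
    out["ECP"] = ecp
    out["ENP"] = enp
    out["x"] = ecp
    out["y"] = ecn
    out["vector_length"] = length
    out["vector_angle"] = angle
    out["angle_class"] = [classify_angle(a) for a in np.atleast_1d(angle)]
    out["quadrant_class"] = [
        quadrant_classify(b, n, l, p)
        for b, n, l, p in zip(act["BG"], act["NAG"], act["LAP"], act["ALP"])
    ]
    return out.reset_index(drop=True)


def summarize_cells(
    stoich: pd.DataFrame,
    quantities: list[str] | None = None,
    keys: tuple[str, str] = ("zone", "depth_layer"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell mean/sd/se/n plus grand means over cells.

    The grand mean of each quantity is the unweighted mean of the cell
    means — on the balanced factorial design this equals the sample-level
    mean; an unbalanced table triggers a warning but is still summarized.
    """
    if quantities is None:
        quantities = [q for q in STOICH_QUANTITIES if q in stoich.columns]
    missing = [k for k in keys if k not in stoich.columns]
    if missing:
        raise ValueError(f"missing key columns: {missing}")
    grouped = stoich.groupby(list(keys), sort=False, observed=True)
    counts = grouped.size()
    if counts.min() < 1:
        raise ValueError("empty cells present")
    if counts.nunique() > 1:
        logger.warning(
            "unbalanced design (cell sizes %s); grand means are unweighted "
            "means of cell means", sorted(counts.unique())
        )
    rows = []
    for cell, sub in grouped:
        for q in quantities:
            v = sub[q].to_numpy(dtype=float)
            n = len(v)
            sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
            rows.append({
                keys[0]: cell[0], keys[1]: cell[1], "quantity": q,
                "mean": float(np.mean(v)), "sd": sd,
                "se": sd / math.sqrt(n) if n > 1 else float("nan"), "n": n,
            })
    cells = pd.DataFrame(rows)
    grand = {
        q: float(cells.loc[cells["quantity"] == q, "mean"].mean())
        for q in quantities
    }
    return cells, grand
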