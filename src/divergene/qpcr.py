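"""Relative quantification of qPCR crossing points (2^-ddCt) and the
in situ hybridization signal arithmetic.

A crossing point (Cp) is the cycle at which a well's fluorescence
crosses threshold; one cycle corresponds to a two-fold template
difference under the method's perfect-doubling assumption.  Duplicate
wells are averaged on the Cp scale, expression is normalized to one
housekeeping gene or to the arithmetic-mean Cp of a pair (the geometric
mean of their expressions), and fold-regulation values are reported
relative to the mean of the group displaying the lowest expression, so
the reference group's fold is exactly 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["ddct_quantify", "fold_regulation", "ish_quantify", "read_cp_table"]


def _validate_plate(plate: pd.DataFrame) -> None:
    required = {"gene", "sample", "group", "replicate", "Cp"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"Cp table missing columns {sorted(missing)}")
    cp = plate["Cp"].to_numpy(float)
    if not np.all(np.isfinite(cp)) or (cp <= 0).any():
        raise ValueError("Cp values must be positive and finite")


def ddct_quantify(plate: pd.DataFrame, gene: str,
                  hk_choice: str | tuple[str, str]) -> pd.DataFrame:
    """Per-sample relative expression of ``gene``, housekeeping-normalized.

    Duplicate wells are averaged on the Cp scale first.  dCt(sample) =
    Cp(gene) - ref(sample), where ref is the Cp of the single
    housekeeping gene or the arithmetic mean Cp of the chosen pair;
    relative expression = 2^-dCt (calibration to ddCt happens at the
    fold-regulation stage).  Samples missing a housekeeping well are
    dropped with a warning.
    """
    _validate_plate(plate)
    hk = (hk_choice,) if isinstance(hk_choice, str) else tuple(hk_choice)
    if len(hk) not in (1, 2):
        raise ValueError("hk_choice must be one gene or a pair")
    mean_cp = (plate.groupby(["gene", "sample", "group"], sort=False)["Cp"]
               .mean().reset_index())
    target = mean_cp[mean_cp["gene"] == gene].set_index("sample")
    if target.empty:
        raise ValueError(f"gene {gene!r} not on plate")
    refs = []
    for h in hk:
        r = mean_cp[mean_cp["gene"] == h].set_index("sample")["Cp"]
        if r.empty:
            raise ValueError(f"housekeeping gene {h!r} not on plate")
        refs.append(r)
    ref = sum(r.reindex(target.index) for r in refs) / len(refs)
    missing = ref.index[ref.isna()]
    if len(missing):
        warnings.warn(f"samples dropped (missing housekeeping well): "
                      f"{list(missing)}")
    keep = ~ref.isna()
    dct = target.loc[keep, "Cp"] - ref[keep]
    return pd.DataFrame({
        "sample": dct.index,
        "group": target.loc[keep, "group"].to_numpy(),
        "dCt": dct.to_numpy(),
        "rel_expr": 2.0 ** (-dct.to_numpy()),
    }).reset_index(drop=True)


def fold_regulation(expressions: pd.DataFrame) -> pd.DataFrame:
    """Group fold-regulation relative to the lowest-expressing group.

    ``expressions`` needs columns group and rel_expr (per sample).  The
    reference is the group with the smallest mean expression (ties
    broken by group-label order, logged); fold(group) = mean(group) /
    mean(reference), so the reference fold is exactly 1.  Dispersion is
    the SEM of per-sample folds.
    """
    if "group" not in expressions or "rel_expr" not in expressions:
        raise ValueError("need columns 'group' and 'rel_expr'")
    means = expressions.groupby("group")["rel_expr"].mean().sort_index()
    if means.empty:
        raise ValueError("no groups")
    lowest = means[means == means.min()]
    if len(lowest) > 1:
        warnings.warn(f"tie in lowest mean expression; using "
                      f"{lowest.index[0]!r} (first by label order)")
    ref_group = lowest.index[0]
    ref_mean = means[ref_group]
    rows = []
    for g, sub in expressions.groupby("group"):
        folds = sub["rel_expr"].to_numpy() / ref_mean
        n = len(folds)
        sem = folds.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rows.append((g, means[g] / ref_mean, sem, n))
    out = pd.DataFrame(rows, columns=["group", "fold", "sem", "n"])
    out.attrs["reference_group"] = ref_group
    return out


def ish_quantify(signal_readings) -> float:
    """In situ hybridization expression value for one individual.

    ``signal_readings``: iterable of (section, region_signal,
    background_signal) with 3-6 sections per individual in the emulated
    protocol (a single section is accepted).  Per-section value is the
    region signal minus the background of a nearby non-expressing
    structure; the maximum across sections is the expression value.  A
    non-positive result (background >= signal everywhere) is returned
    as-is with a warning.
    """
    readings = [(s, float(sig), float(bg)) for s, sig, bg in signal_readings]
    if not readings:
        raise ValueError("no sections")
    for _, sig, bg in readings:
        if sig < 0 or bg < 0:
            raise ValueError("signals must be >= 0")
    value = max(sig - bg for _, sig, bg in readings)
    if value <= 0:
        warnings.warn("background >= signal in all sections")
    return value


def read_cp_table(path) -> pd.DataFrame:
    """Read a Cp CSV (gene, sample, group, replicate, Cp)."""
    plate = pd.read_csv(path)
    _validate_plate(plate)
    return plate
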