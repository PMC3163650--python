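"""Cross-region candidate-gene selection.

Operates on a bundle of per-region differential-expression tables whose
``fold_pct`` column is the HAB-relative-to-LAB expression as a percent
(>100 means higher in HAB).  "Percent regulation" is the fold ratio
oriented in the regulation direction: ``(max(r, 1/r) - 1) * 100``, so a
1.4-fold change in either direction counts as 40% regulation.

Two selection rules are implemented and must be chosen explicitly:

* strictA -- at least 40% regulation in one region with adjusted
  p < 0.05 there, and at least 30% regulation in every other region;
* strictB -- at least 30% regulation with adjusted p < 0.10 in all, or
  in at least three, of the analyzed regions.

Regulation must point the same way in every region where the probe shows
it; probes regulated oppositely across regions are excluded from the
cross-region track and surfaced by :func:`direction_report` instead.
Probes absent from a region's table are treated as failing that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionRule", "RULE_A", "RULE_B", "regulation_pct",
           "select_candidates", "direction_report"]


@dataclass(frozen=True)
class SelectionRule:
    rule_id: str
    primary_threshold: float  # percent regulation in the best region
    secondary_threshold: float  # percent regulation elsewhere
    p_threshold: float
    region_coverage: str  # "all" | "at-least-3"

    def __post_init__(self) -> None:
        if self.primary_threshold <= 0 or self.secondary_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.region_coverage not in ("all", "at-least-3"):
            raise ValueError("region_coverage must be 'all' or 'at-least-3'")


RULE_A = SelectionRule("strictA", primary_threshold=40.0,
                       secondary_threshold=30.0, p_threshold=0.05,
                       region_coverage="all")
RULE_B = SelectionRule("strictB", primary_threshold=30.0,
                       secondary_threshold=30.0, p_threshold=0.10,
                       region_coverage="at-least-3")


def regulation_pct(fold_pct: np.ndarray) -> np.ndarray:
    """Percent regulation of a HAB/LAB percent fold, direction-fair."""
    r = np.asarray(fold_pct, float) / 100.0
    with np.errstate(divide="ignore"):
        return (np.maximum(r, 1.0 / r) - 1.0) * 100.0


def _bundle_frames(bundle: dict[str, pd.DataFrame]
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Pivot a region->DE-table map into probe x region fold/p/sign frames."""
    if not bundle:
        raise ValueError("empty region bundle")
    if len(bundle) != len(set(bundle)):
        raise ValueError("duplicate region")
    regions = sorted(bundle)
    folds, ps = {}, {}
    for reg in regions:
        t = bundle[reg].set_index("probe_id")
        folds[reg] = t["fold_pct"]
        ps[reg] = t["p_adj"]
    fold = pd.DataFrame(folds)
    p = pd.DataFrame(ps).reindex(fold.index)
    sign = np.sign(np.log(fold / 100.0))
    return fold, p, sign, regions


def select_candidates(bundle: dict[str, pd.DataFrame],
                      rule: SelectionRule) -> pd.DataFrame:
    """Apply a selection rule across regions; output sorted by max regulation.

    Returns one row per selected probe with per-region folds and
    adjusted p-values, the number of passing regions, and the direction.
    Direction-inconsistent probes (opposite regulation in regions that
    show any) are excluded and flagged in the ``excluded`` attribute of
    the returned frame (``result.attrs['direction_inconsistent']``).
    """
    fold, p, sign, regions = _bundle_frames(bundle)
    reg = pd.DataFrame(regulation_pct(fold.to_numpy()),
                       index=fold.index, columns=fold.columns)
    # direction consistency among regions with a measured, nonzero fold
    pos = (sign > 0).sum(axis=1)
    neg = (sign < 0).sum(axis=1)
    inconsistent = (pos > 0) & (neg > 0)

    reg_f = reg.fillna(-np.inf)
    p_f = p.fillna(1.0)
    if rule.rule_id == "strictA":
        primary = (reg_f >= rule.primary_threshold) & (p_f < rule.p_threshold)
        secondary = reg_f >= rule.secondary_threshold
        # every region must clear the secondary bar, and at least one
        # region must clear the primary bar with significance
        passed = primary.any(axis=1) & secondary.all(axis=1)
        n_passed = secondary.sum(axis=1)
    else:
        ok = (reg_f >= rule.secondary_threshold) & (p_f < rule.p_threshold)
        n_passed = ok.sum(axis=1)
        need = len(regions) if rule.region_coverage == "all" else min(3, len(regions))
        passed = n_passed >= need
    sel = passed & ~inconsistent
    out = pd.DataFrame({
        "probe_id": fold.index[sel],
        "max_regulation_pct": reg[sel].max(axis=1).to_numpy(),
        "n_regions_passed": n_passed[sel].to_numpy(),
        "direction": np.where(pos[sel] > 0, "up_in_HAB", "down_in_HAB"),
    })
    for r in regions:
        out[f"fold_{r}"] = fold.loc[sel, r].to_numpy()
        out[f"p_{r}"] = p.loc[sel, r].to_numpy()
    out = out.sort_values("max_regulation_pct", ascending=False,
                          kind="stable").reset_index(drop=True)
    out.attrs["direction_inconsistent"] = list(fold.index[inconsistent & passed])
    out.attrs["rule"] = rule
    return out


def direction_report(bundle: dict[str, pd.DataFrame],
                     p_threshold: float = 0.05) -> pd.DataFrame:
    """Probes significantly regulated in opposite directions across regions.

    Mirrors the region-specific candidate track (e.g. a transporter up
    in one amygdalar nucleus and down in a hypothalamic one): lists every
    probe whose mean-M sign differs between two regions that are both
    below ``p_threshold``.
    """
    if len(bundle) < 2:
        raise ValueError("need at least 2 regions")
    fold, p, sign, regions = _bundle_frames(bundle)
    sig = (p < p_threshold) & fold.notna()
    sig_pos = ((sign > 0) & sig).sum(axis=1)
    sig_neg = ((sign < 0) & sig).sum(axis=1)
    hit = (sig_pos > 0) & (sig_neg > 0)
    rows = []
    for probe in fold.index[hit]:
        up = [r for r in regions if sig.loc[probe, r] and sign.loc[probe, r] > 0]
        down = [r for r in regions if sig.loc[probe, r] and sign.loc[probe, r] < 0]
        rows.append((probe, ",".join(up), ",".join(down)))
    return pd.DataFrame(rows, columns=["probe_id", "up_regions", "down_regions"])
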