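"""Position-dependent inhibition rates and the on-target / out-of-window contrast.

The inhibition rate at protospacer position p compares a treated (inhibitor)
condition with its control:

    IR(p) = 1 - f_treated(p) / f_control(p)

computed only where the control frequency is at least ``min_control_freq``
(ratios against near-zero controls are noise).  The reported IR is clamped to
[0, 1] — matching heat-map semantics where enhancement beyond control or
sampling noise below zero is truncated — while the raw value is retained for
diagnostics.  Window focusing is summarised by the selectivity fold, the
ratio of mean out-of-window IR to mean on-target IR, with a two-tailed
equal-variance Student's t test between the two groups of IR values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import EditingProfile
from .targets import PROTOSPACER_LEN, WindowPartition

__all__ = [
    "InhibitionProfile",
    "WindowComparison",
    "inhibition_rate",
    "window_comparison",
    "student_t_two_tailed",
    "heatmap_table",
    "profiles_from_table",
]


@dataclass
class InhibitionProfile:
    """Per-position inhibition rates for one control/treated pair."""

    site: str
    ir: np.ndarray       # (20,) clamped to [0, 1]; NaN where undefined
    ir_raw: np.ndarray   # (20,) unclamped
    control_label: str = ""
    treated_label: str = ""
    replicate: int = 0

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.ir)


@dataclass
class WindowComparison:
    """On-target vs out-of-window inhibition contrast."""

    on_values: np.ndarray
    out_values: np.ndarray
    mean_on: float
    mean_out: float
    selectivity_fold: float  # NaN when undefined
    t_statistic: float
    p_value: float
    n_on: int
    n_out: int
    reason: str = ""  # non-empty when fold/test is undefined


def inhibition_rate(control: EditingProfile, treated: EditingProfile,
                    min_control_freq: float = 0.005, site: str = "",
                    replicate: int = 0) -> InhibitionProfile:
    """IR(p) = 1 - f_treated / f_control where the control is quantifiable."""
    if control.editor != treated.editor:
        raise ValueError("control and treated profiles use different editors")
    fc, ft = control.freqs, treated.freqs
    ok = (~np.isnan(fc)) & (~np.isnan(ft)) & (fc >= min_control_freq)
    raw = np.full(PROTOSPACER_LEN, np.nan)
    raw[ok] = 1.0 - ft[ok] / fc[ok]
    clamped = np.clip(raw, 0.0, 1.0)
    return InhibitionProfile(site, clamped, raw,
                             control.label, treated.label, replicate)


def student_t_two_tailed(x, y, equal_var: bool = True):
    """Two-sample two-tailed Student's t test (pooled variance by default).

    Returns ``(t, p)``.  Raises :class:`ValueError` if either group has
    fewer than two values.  Zero-variance degenerate groups are handled
    explicitly: equal means give (0, 1), unequal means (inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values for a t test")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def window_comparison(profiles, partition: WindowPartition,
                      equal_var: bool = True) -> WindowComparison:
    """Pool defined IR values by window group and contrast them.

    ``profiles`` may be a single :class:`InhibitionProfile` or an iterable
    (replicates and/or sites pooled into the two groups).
    """
    if isinstance(profiles, InhibitionProfile):
        profiles = [profiles]
    on_idx = np.array(sorted(partition.on_target)) - 1
    out_idx = np.array(sorted(partition.out_of_window)) - 1
    on_vals, out_vals = [], []
    for prof in profiles:
        on_vals.extend(prof.ir[on_idx][~np.isnan(prof.ir[on_idx])])
        out_vals.extend(prof.ir[out_idx][~np.isnan(prof.ir[out_idx])])
    on_vals = np.asarray(on_vals)
    out_vals = np.asarray(out_vals)

    reason = ""
    if len(on_vals) == 0 or len(out_vals) == 0:
        return WindowComparison(on_vals, out_vals, np.nan, np.nan, np.nan,
                                np.nan, np.nan, len(on_vals), len(out_vals),
                                reason="empty window group: no defined IR values")
    mean_on = float(on_vals.mean())
    mean_out = float(out_vals.mean())
    if mean_on > 0:
        fold = mean_out / mean_on
    else:
        fold, reason = np.nan, "on-target mean IR is zero; fold undefined"
    try:
        t, p = student_t_two_tailed(out_vals, on_vals, equal_var=equal_var)
    except ValueError as exc:
        t, p, reason = np.nan, np.nan, str(exc)
    return WindowComparison(on_vals, out_vals, mean_on, mean_out, fold, t, p,
                            len(on_vals), len(out_vals), reason)


def heatmap_table(profiles) -> pd.DataFrame:
    """Long-format (site, replicate, position, ir) table for heat-map plotting.

    All 20 positions are emitted per profile; masked positions carry NaN.
    """
    if isinstance(profiles, InhibitionProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for p in range(1, PROTOSPACER_LEN + 1):
            rows.append({"site": prof.site, "replicate": prof.replicate,
                         "position": p, "ir": prof.ir[p - 1]})
    return pd.DataFrame(rows)


def profiles_from_table(table: pd.DataFrame):
    """Rebuild :class:`InhibitionProfile` objects from a heat-map table."""
    profiles = []
    for (site, rep), grp in table.groupby(["site", "replicate"], sort=False):
        ir = np.full(PROTOSPACER_LEN, np.nan)
        for _, row in grp.iterrows():
            ir[int(row["position"]) - 1] = row["ir"]
        profiles.append(InhibitionProfile(site, ir, ir.copy(), replicate=int(rep)))
    return profiles
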