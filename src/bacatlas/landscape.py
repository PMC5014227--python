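"""Sliding-window gene-density / recombination landscapes along chromosomes
and detection of deviant (gene-dense, recombination-suppressed) regions.

Windows of ``window`` bp advance by ``step`` bp from position 0 of each
chromosome; a BAC belongs to every window containing its anchor coordinate.
Per window the track records the BAC count, the proportions of BACs with 0,
exactly 1 and >= 3 high-confidence gene models, gene density GD (unique HC
models among the window's BACs per BAC) and recombination frequency RF
(cM span / Mb span of the window's BACs). Deviant regions are windows in
the top GD quantile and bottom RF quantile simultaneously, merged when
overlapping or adjacent — the scale-free analogue of reading a red-on-green
landscape heat map by eye.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError


@dataclass
class LandscapeConfig:
    window: int = 40_000_000
    step: int = 2_500_000
    gd_quantile: float = 0.75
    rf_quantile: float = 0.25
    min_bacs_per_window: int = 5

    def validate(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ConfigurationError("window and step must be >= 1")
        if self.step > self.window:
            raise ConfigurationError("step must be <= window")
        for nm, q in (("gd_quantile", self.gd_quantile), ("rf_quantile", self.rf_quantile)):
            if not 0 < q < 1:
                raise ConfigurationError(f"{nm} must be in (0, 1)")
        if self.min_bacs_per_window < 1:
            raise ConfigurationError("min_bacs_per_window must be >= 1")


def _models_of(value) -> frozenset:
    """Parse the hc_models cell: semicolon-joined string, iterable, or empty."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    if isinstance(value, str):
        return frozenset(m for m in value.split(";") if m)
    return frozenset(value)


def _check_monotone_map(anchored: pd.DataFrame) -> None:
    for chrom, sub in anchored.groupby("chrom", sort=False):
        s = sub.sort_values("bp", kind="stable")
        if (np.diff(s["cM"].to_numpy(float)) < -1e-9).any():
            raise DataError(f"genetic map on {chrom} is not monotone in bp")


def _window_starts(length: int, config: LandscapeConfig) -> np.ndarray:
    return np.arange(0, max(length, 1), config.step, dtype=np.int64)


def window_stats(
    anchored: pd.DataFrame,
    config: LandscapeConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window landscape statistics.

    ``anchored`` columns: bac_id, chrom, bp, cM, hc_models (semicolon-joined
    model ids, post frequent-model exclusion; empty for zero-gene BACs).
    Windows whose BAC count is below ``min_bacs_per_window`` report NaN GD
    and RF; RF is also NaN when all member BACs share one bp (zero span).
    The last, partial window of each chromosome is emitted with partial=True.
    """
    config = config or LandscapeConfig()
    config.validate()
    _check_monotone_map(anchored)

    rows = []
    for chrom, sub in anchored.groupby("chrom", sort=True):
        bp = sub["bp"].to_numpy(np.int64)
        cm = sub["cM"].to_numpy(float)
        model_sets = [_models_of(v) for v in sub["hc_models"]]
        n_models = np.array([len(s) for s in model_sets])
        length = (
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths else int(bp.max()) + 1
        )
        for start in _window_starts(length, config):
            end = start + config.window
            partial = end > length
            inside = np.flatnonzero((bp >= start) & (bp < end))
            n = inside.size
            if n == 0:
                p0 = p1 = p3 = np.nan
                gd = rf = np.nan
            else:
                counts = n_models[inside]
                p0 = float((counts == 0).mean())
                p1 = float((counts == 1).mean())
                p3 = float((counts >= 3).mean())
                if n < config.min_bacs_per_window:
                    gd = rf = np.nan
                else:
                    union = frozenset().union(*(model_sets[i] for i in inside))
                    gd = len(union) / n
                    span_mb = (bp[inside].max() - bp[inside].min()) / 1e6
                    rf = (cm[inside].max() - cm[inside].min()) / span_mb if span_mb > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(min(end, length)),
                    "center_bp": int(start + config.window // 2),
                    "n_bacs": int(n),
                    "p0": p0,
                    "p1": p1,
                    "p3plus": p3,
                    "gd": gd,
                    "rf": rf,
                    "partial": bool(partial),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "center_bp", "n_bacs", "p0", "p1", "p3plus", "gd", "rf", "partial"],
    )


def detect_deviant_regions(
    stats: pd.DataFrame, config: LandscapeConfig | None = None
) -> pd.DataFrame:
    """Merge windows that are simultaneously gene-dense (GD >= genome-wide
    gd_quantile) and recombination-suppressed (RF <= rf_quantile).

    Thresholds are quantiles over all non-missing windows genome-wide, so
    the rule adapts to the data's scale. Qualifying windows on one
    chromosome merge when they overlap or touch.
    """
    config = config or LandscapeConfig()
    config.validate()
    ok = stats.dropna(subset=["gd", "rf"])
    if ok.empty:
        warnings.warn("detect_deviant_regions: no windows with data", stacklevel=2)
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mean_gd", "mean_rf", "n_windows"]
        )
    gd_thr = float(ok["gd"].quantile(config.gd_quantile))
    rf_thr = float(ok["rf"].quantile(config.rf_quantile))
    hot = ok[(ok["gd"] >= gd_thr) & (ok["rf"] <= rf_thr)]

    regions = []
    for chrom, sub in hot.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur = None
        for _, w in sub.iterrows():
            if cur is not None and w["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["gds"].append(w["gd"])
                cur["rfs"].append(w["rf"])
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "gds": [w["gd"]],
                    "rfs": [w["rf"]],
                }
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(
        [
            {
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "mean_gd": float(np.mean(r["gds"])),
                "mean_rf": float(np.mean(r["rfs"])),
                "n_windows": len(r["gds"]),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "mean_gd", "mean_rf", "n_windows"],
    )


def bac_density_track(
    anchored: pd.DataFrame,
    config: LandscapeConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window BAC counts (the grey-bar track of a clone-density plot).

    An interior BAC contributes to exactly ceil(window/step) windows; fewer
    at the chromosome edges.
    """
    config = config or LandscapeConfig()
    config.validate()
    rows = []
    for chrom, sub in anchored.groupby("chrom", sort=True):
        bp = sub["bp"].to_numpy(np.int64)
        length = (
            chrom_lengths[chrom] if chrom_lengths and chrom in chrom_lengths else int(bp.max()) + 1
        )
        for start in _window_starts(length, config):
            n = int(((bp >= start) & (bp < start + config.window)).sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "center_bp": int(start + config.window // 2),
                    "n_bacs": n,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "center_bp", "n_bacs"])
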