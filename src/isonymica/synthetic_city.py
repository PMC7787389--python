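"""Synthetic person-record tables with planted group structure.

Every downstream stage of the package (surname-pair networks, spatial
isonymy grids, community detection) can be validated against the ground
truth planted here: surname pools per group, tunable endogamy in surname
pairing, group-specific spatial concentration, and block-level income
correlated with group membership.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from isonymica.communities import Partition

__all__ = ["CityConfig", "generate_city", "planted_partition", "write_records", "load_config"]

RECORD_COLUMNS = [
    "paternal_surname",
    "maternal_surname",
    "x",
    "y",
    "block_id",
    "block_income",
    "group_label",
]


@dataclass
class CityConfig:
    """Parameters of a synthetic city.

    ``grid_extent`` is ``(x_min, x_max, y_min, y_max)``. ``group_centers``
    must lie inside the extent; ``group_spread`` and ``ses_group_means``
    are per-group (a scalar spread is broadcast).
    """

    n_persons: int = 10_000
    n_groups: int = 4
    surnames_per_group: int = 50
    zipf_exponent: float = 1.0
    endogamy: float = 0.9
    grid_extent: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0)
    group_centers: Sequence[tuple[float, float]] | None = None
    group_spread: float | Sequence[float] = 0.08
    block_size: float = 0.05
    ses_group_means: Sequence[float] | None = None
    ses_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_persons", "n_groups", "surnames_per_group"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("zipf_exponent", "endogamy", "block_size", "ses_noise_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.endogamy <= 1.0:
            raise ValueError(f"endogamy must lie in [0, 1], got {self.endogamy!r}")
        if self.zipf_exponent <= 0:
            raise ValueError(f"zipf_exponent must be positive, got {self.zipf_exponent!r}")
        if self.block_size <= 0:
            raise ValueError(f"block_size must be positive, got {self.block_size!r}")
        if self.ses_noise_sd < 0:
            raise ValueError(f"ses_noise_sd must be non-negative, got {self.ses_noise_sd!r}")

        x0, x1, y0, y1 = (float(v) for v in self.grid_extent)
        if not all(map(math.isfinite, (x0, x1, y0, y1))) or x1 <= x0 or y1 <= y0:
            raise ValueError(f"grid_extent must be a finite non-empty box, got {self.grid_extent!r}")
        self.grid_extent = (x0, x1, y0, y1)

        if self.group_centers is None:
            # evenly spaced on a ring inside the extent
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            r = 0.3 * min(x1 - x0, y1 - y0)
            self.group_centers = tuple(
                (cx + r * math.cos(2 * math.pi * g / self.n_groups),
                 cy + r * math.sin(2 * math.pi * g / self.n_groups))
                for g in range(self.n_groups)
            )
        self.group_centers = tuple((float(a), float(b)) for a, b in self.group_centers)
        if len(self.group_centers) != self.n_groups:
            raise ValueError("group_centers must have one entry per group")
        for g, (gx, gy) in enumerate(self.group_centers):
            if not (math.isfinite(gx) and math.isfinite(gy)):
                raise ValueError(f"group_centers[{g}] must be finite")
            if not (x0 <= gx <= x1 and y0 <= gy <= y1):
                raise ValueError(f"group_centers[{g}]={self.group_centers[g]} outside grid_extent")

        if np.isscalar(self.group_spread):
            self.group_spread = tuple([float(self.group_spread)] * self.n_groups)
        else:
            self.group_spread = tuple(float(s) for s in self.group_spread)
        if len(self.group_spread) != self.n_groups:
            raise ValueError("group_spread must be scalar or one value per group")
        for g, s in enumerate(self.group_spread):
            if not (math.isfinite(s) and s > 0):
                raise ValueError(f"group_spread[{g}] must be a positive finite real")

        if self.ses_group_means is None:
            self.ses_group_means = tuple(100.0 * (g + 1) / self.n_groups for g in range(self.n_groups))
        self.ses_group_means = tuple(float(m) for m in self.ses_group_means)
        if len(self.ses_group_means) != self.n_groups:
            raise ValueError("ses_group_means must have one value per group")
        for g, m in enumerate(self.ses_group_means):
            if not math.isfinite(m):
                raise ValueError(f"ses_group_means[{g}] must be finite")


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    """Normalized finite-pool power law over ranks 1..n."""
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def surname_token(group: int, rank: int) -> str:
    """Synthetic surname: group ``group``, within-pool rank ``rank`` (1-based)."""
    return f"G{group}_S{rank}"


def generate_city(config: CityConfig) -> pd.DataFrame:
    """Generate a person-record table from ``config``.

    For each person a group is sampled uniformly. Each surname slot is
    drawn from the person's own group pool with probability ``endogamy``,
    otherwise from a uniformly chosen group pool; within a pool, surname
    identity follows the configured power law over ranks. Locations are
    per-axis truncated Gaussians around the group center. ``block_income``
    is the configured mean of the block's modal group plus one Gaussian
    draw per block, so it is constant within a block.

    Pure function of ``config`` (including ``seed``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    k = config.n_groups
    x0, x1, y0, y1 = config.grid_extent

    group = rng.integers(0, k, size=n)

    pool_probs = _zipf_probs(config.surnames_per_group, config.zipf_exponent)

    def draw_slot() -> tuple[np.ndarray, np.ndarray]:
        own = rng.random(n) < config.endogamy
        src = np.where(own, group, rng.integers(0, k, size=n))
        rank = rng.choice(config.surnames_per_group, size=n, p=pool_probs) + 1
        return src, rank

    pat_src, pat_rank = draw_slot()
    mat_src, mat_rank = draw_slot()

    centers = np.asarray(config.group_centers)
    spreads = np.asarray(config.group_spread)

    def truncated_axis(center: np.ndarray, sd: np.ndarray, lo: float, hi: float) -> np.ndarray:
        a = (lo - center) / sd
        b = (hi - center) / sd
        return stats.truncnorm.rvs(a, b, loc=center, scale=sd, random_state=rng)

    xs = truncated_axis(centers[group, 0], spreads[group], x0, x1)
    ys = truncated_axis(centers[group, 1], spreads[group], y0, y1)

    bx = np.minimum(((xs - x0) / config.block_size).astype(int),
                    max(int(np.ceil((x1 - x0) / config.block_size)) - 1, 0))
    by = np.minimum(((ys - y0) / config.block_size).astype(int),
                    max(int(np.ceil((y1 - y0) / config.block_size)) - 1, 0))
    block_ids = np.array([f"B{i}_{j}" for i, j in zip(bx, by)])

    df = pd.DataFrame(
        {
            "paternal_surname": [surname_token(g, r) for g, r in zip(pat_src, pat_rank)],
            "maternal_surname": [surname_token(g, r) for g, r in zip(mat_src, mat_rank)],
            "x": xs,
            "y": ys,
            "block_id": block_ids,
            "group_label": [f"group{g}" for g in group],
        }
    )

    # one income draw per block: modal group mean + noise (ties -> lowest group)
    means = np.asarray(config.ses_group_means)
    block_income: dict[str, float] = {}
    modal = (
        df.assign(_g=group)
        .groupby("block_id")["_g"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
    )
    for bid in sorted(modal.index):
        noise = rng.normal(0.0, config.ses_noise_sd) if config.ses_noise_sd > 0 else 0.0
        block_income[bid] = float(means[modal[bid]] + noise)
    df["block_income"] = df["block_id"].map(block_income)
    return df[RECORD_COLUMNS]


def planted_partition(records: pd.DataFrame) -> Partition:
    """Ground-truth partition of surnames into their generating pools.

    Requires synthetic records (``group_label`` column present). Surname
    tokens encode their pool, so the partition is recoverable even for
    surnames that only appear through exogamous draws.
    """
    if "group_label" not in records.columns or records["group_label"].isna().any():
        raise ValueError("planted_partition requires synthetic records with group_label")
    labels: dict[str, int] = {}
    for col in ("paternal_surname", "maternal_surname"):
        for s in records[col].unique():
            labels[s] = int(s.split("_")[0][1:])
    return Partition(labels, modularity=None, n_runs=1, method="planted")


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as UTF-8 comma-separated text with a header row."""
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False, encoding="utf-8")


def load_config(path: str | Path) -> CityConfig:
    """Load a :class:`CityConfig` from a YAML or JSON document."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "grid_extent" in data:
        data["grid_extent"] = tuple(data["grid_extent"])
    if data.get("group_centers") is not None:
        data["group_centers"] = [tuple(c) for c in data["group_centers"]]
    return CityConfig(**data)
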