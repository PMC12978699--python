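"""Synthetic data generators emulating lineage-labeled cyst measurements.

Three kinds of fixture data are produced, all seeded and reproducible:

* measurement tables — per-cell fusome volume, Pard3 area, bridge count and
  nucleus diameter across cysts of chosen sizes, with the statistical
  structure (sister asymmetry, bridge-count enrichment) the inheritance
  model imposes;
* MT-gap datasets — cysts of 7-10 cells each carrying one bridge that lacks
  a stabilized-microtubule connection, placed at a 6-cell-releasing bridge
  (programmed truth, up to a miscall rate) or uniformly (random truth);
* voxelized granules — labeled 3-D arrays of spheres for validating
  voxel-count volume measurement against the analytic volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from cystkit.fragmentation import six_yielding_bridges
from cystkit.fusome import FusomeParams, simulate_fusome
from cystkit.topology import (
    Bridge,
    CystGraph,
    PartialRoundPolicy,
    fragment_sizes,
    partial_cyst,
)

Truth = Literal["programmed", "random"]

#: cyst-size composition of the published 15-cyst MT-gap sample
PUBLISHED_SIZE_MIX: dict[int, int] = {7: 3, 8: 8, 9: 1, 10: 3}


# -- measurement tables ----------------------------------------------------


def make_measurement_table(
    stage_mix: Optional[dict[int, int]] = None,
    params: Optional[FusomeParams] = None,
    nucleus_diameter_um: float = 8.0,
    nucleus_sigma: float = 0.1,
    pard3_scale_um2: float = 4.0,
    pard3_sigma: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell measurement table across cysts of the requested sizes.

    ``stage_mix`` maps cyst size to the number of cysts of that size
    (default: sixteen 2-cell and eight 8-cell cysts).  Fusome volumes come
    from the inheritance simulator; Pard3 area mirrors fusome volume with
    independent lognormal noise; nucleus diameters are lognormal around a
    typical fetal germ-cell value.  Fixed seed -> identical table.
    """
    if stage_mix is None:
        stage_mix = {2: 16, 8: 8}
    if params is None:
        params = FusomeParams()
    rng = np.random.default_rng(seed)
    rows = []
    cyst_id = 0
    graphs: dict[int, CystGraph] = {}
    for size in sorted(stage_mix):
        for _ in range(stage_mix[size]):
            cyst_id += 1
            g = graphs.setdefault(size, partial_cyst(size))
            state = simulate_fusome(g, params, rng)
            for cell in sorted(g.cells):
                vol = state[cell]
                rows.append(
                    {
                        "cyst_id": cyst_id,
                        "cell_id": cell,
                        "stage_label": f"{size}-cell",
                        "n_bridges": g.degree_of(cell),
                        "fusome_volume_um3": vol,
                        "pard3_area_um2": pard3_scale_um2
                        * vol
                        * rng.lognormal(0.0, pard3_sigma),
                        "nucleus_diameter_um": nucleus_diameter_um
                        * rng.lognormal(0.0, nucleus_sigma),
                    }
                )
    return pd.DataFrame(rows)


def write_measurement_csv(
    df: pd.DataFrame, path: str | Path, seed: Optional[int] = None
) -> None:
    """Write a measurement table as CSV (UTF-8, header, '.' decimal).

    When ``seed`` is given, a sidecar ``<path>.meta.json`` records it.
    """
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    if seed is not None:
        meta = {"seed": seed, "rows": int(len(df))}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )


# -- MT-gap datasets -------------------------------------------------------


@dataclass(frozen=True)
class MtGapRecord:
    """One lineage-labeled cyst with its microtubule-gap bridge.

    ``six_predicted`` is always derived from the topology, never stored:
    it is true exactly when removing the gap bridge releases a 6-cell
    fragment.
    """

    cyst_id: int
    graph: CystGraph
    gap_edge: Bridge

    @property
    def cyst_size(self) -> int:
        return self.graph.n_cells

    @property
    def six_predicted(self) -> bool:
        return 6 in fragment_sizes(self.graph, self.gap_edge)


def make_mt_gap_dataset(
    size_mix: dict[int, int],
    truth: Truth,
    miscall_rate: float = 0.0,
    policy: PartialRoundPolicy = "leaf_first",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[MtGapRecord]:
    """Cysts with one MT-gap bridge each, under a chosen ground truth.

    ``programmed`` places the gap at a 6-cell-releasing bridge with
    probability 1 - miscall_rate, otherwise uniformly among the remaining
    bridges; if the topology admits no 6-cell cut the gap falls uniformly
    on any bridge.  ``random`` places the gap uniformly over all bridges.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 0.0 <= miscall_rate <= 1.0:
        raise ValueError("miscall_rate must lie in [0, 1]")
    if truth not in ("programmed", "random"):
        raise ValueError(f"unknown truth {truth!r}")
    pools: dict[int, tuple[CystGraph, list[Bridge], list[Bridge], list[Bridge]]] = {}
    records: list[MtGapRecord] = []
    cyst_id = 0
    for size in sorted(size_mix):
        for _ in range(size_mix[size]):
            cyst_id += 1
            if policy == "leaf_first" and size in pools:
                g, bridges, six_edges, other_edges = pools[size]
            else:
                g = partial_cyst(size, policy, rng=rng)
                bridges = g.bridges
                six_edges = [o.bridge for o in six_yielding_bridges(g)]
                other_edges = [b for b in bridges if b not in six_edges]
                if policy == "leaf_first":
                    pools[size] = (g, bridges, six_edges, other_edges)
            if truth == "random" or not six_edges:
                pool = bridges
            elif other_edges and rng.random() < miscall_rate:
                pool = other_edges
            else:
                pool = six_edges
            gap = pool[int(rng.integers(len(pool)))]
            records.append(MtGapRecord(cyst_id, g, gap))
    return records


def mt_gap_dataframe(records: Sequence[MtGapRecord]) -> pd.DataFrame:
    """Tidy view of an MT-gap dataset (one row per cyst)."""
    return pd.DataFrame(
        {
            "cyst_id": [r.cyst_id for r in records],
            "cyst_size": [r.cyst_size for r in records],
            "gap_cell_a": [r.gap_edge.cell_a for r in records],
            "gap_cell_b": [r.gap_edge.cell_b for r in records],
            "six_predicted": [r.six_predicted for r in records],
        }
    )


# -- voxelized granules ----------------------------------------------------


@dataclass
class VoxelVolume:
    """Labeled voxel array with its edge length and sphere ground truth."""

    labels: np.ndarray  # 3-D integer array, 0 = background
    voxel_size_um: float
    spheres: list[tuple[tuple[float, float, float], float]]


def voxelize_granules(
    spheres: Sequence[tuple[tuple[float, float, float], float]],
    voxel_size_um: float,
) -> VoxelVolume:
    """Rasterize non-overlapping spheres onto a voxel grid.

    A voxel belongs to sphere i (label i + 1) when its center lies inside
    the sphere.  Overlapping spheres are rejected, so labels are unique.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel size must be > 0")
    spheres = [((float(x), float(y), float(z)), float(r)) for (x, y, z), r in spheres]
    for _, r in spheres:
        if r <= 0:
            raise ValueError("sphere radius must be > 0")
    for i in range(len(spheres)):
        for j in range(i + 1, len(spheres)):
            (c1, r1), (c2, r2) = spheres[i], spheres[j]
            d = np.linalg.norm(np.subtract(c1, c2))
            if d < r1 + r2:
                raise ValueError(f"spheres {i} and {j} overlap")
    h = voxel_size_um
    if not spheres:
        return VoxelVolume(np.zeros((0, 0, 0), dtype=np.int32), h, [])
    lo = np.min([np.subtract(c, r) for c, r in spheres], axis=0) - h
    hi = np.max([np.add(c, r) for c, r in spheres], axis=0) + h
    shape = np.ceil((hi - lo) / h).astype(int)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * h for d in range(3)]
    labels = np.zeros(tuple(shape), dtype=np.int32)
    # rasterize each sphere only inside its bounding sub-box
    for i, (c, r) in enumerate(spheres):
        idx = []
        for d in range(3):
            j0 = int(np.searchsorted(axes[d], c[d] - r))
            j1 = int(np.searchsorted(axes[d], c[d] + r))
            idx.append((j0, j1))
        dx = axes[0][idx[0][0] : idx[0][1]] - c[0]
        dy = axes[1][idx[1][0] : idx[1][1]] - c[1]
        dz = axes[2][idx[2][0] : idx[2][1]] - c[2]
        inside = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
            < r**2
        )
        sub = labels[
            idx[0][0] : idx[0][1], idx[1][0] : idx[1][1], idx[2][0] : idx[2][1]
        ]
        sub[inside] = i + 1
    return VoxelVolume(labels, h, spheres)


def measure_volume(vol: VoxelVolume, label: int) -> float:
    """Volume of one labeled object: voxel count times voxel volume (um^3)."""
    if label <= 0:
        raise ValueError("labels are positive integers")
    return float(np.count_nonzero(vol.labels == label)) * vol.voxel_size_um**3


def export_tiff(vol: VoxelVolume, path: str | Path) -> None:
    """Write the label array as a 3-D TIFF stack (requires tifffile)."""
    import tifffile

    tifffile.imwrite(str(path), vol.labels.astype(np.uint16))
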