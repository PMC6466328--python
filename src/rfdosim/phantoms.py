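"""Voxel phantoms, tissue property tables, mass accounting and model comparison.

The data model of the whole pipeline: a labelled 3-D tissue grid
(:class:`VoxelPhantom`) plus a companion table of per-tissue electrical and
mechanical properties (:class:`TissuePropertyTable`).  On top of those sit
the operations used to compare a detailed reference anatomy with its
tissue-simplified counterpart:

* per-tissue mass accounting (voxel count x voxel volume x density),
* mass-weighted dielectric homogenization, which replaces a group of
  detailed tissues by a single material whose complex permittivity is the
  mass-weighted mean of the constituents' -- mass weighting is linear in
  conductivity ``sigma`` and relative permittivity ``eps_r`` separately,
* weight-deviation and Dice-overlap comparison tables.

Conventions
-----------
Coordinates are 0-based voxel indices; physical positions are voxel centres,
``origin + (index + 0.5) * voxel_size``.  Phantoms are stored on disk as a
raw little-endian integer volume with a JSON sidecar carrying geometry
metadata (the sidecar is the source of truth); NIfTI export is available for
interoperability with image viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissuePropertyTable",
    "VoxelPhantom",
    "TissueGroupMap",
    "TissueMassTable",
    "ModelComparison",
    "read_property_table",
    "read_phantom",
    "write_phantom",
    "export_nifti",
    "tissue_masses",
    "homogenize_dielectrics",
    "compare_models",
    "dice_coefficient",
]

BACKGROUND_LABEL = 0

#: Column schema of every property-table CSV read or written by this module.
PROPERTY_COLUMNS = ("tissue", "label", "sigma_S_per_m", "eps_r", "rho_kg_per_m3")


# ---------------------------------------------------------------------------
# Tissue property table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissuePropertyTable:
    """Per-tissue conductivity, relative permittivity and mass density.

    Wraps a :class:`pandas.DataFrame` with columns ``tissue`` (name),
    ``label`` (unique non-negative integer), ``sigma_S_per_m`` (S/m),
    ``eps_r`` (dimensionless) and ``rho_kg_per_m3`` (kg/m^3).  Exactly one
    row is the background (label 0) with sigma = rho = 0 and eps_r = 1;
    every tissue row has sigma >= 0, eps_r >= 1 and rho > 0.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(PROPERTY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"property table missing columns: {sorted(missing)}")
        df = df.loc[:, list(PROPERTY_COLUMNS)].reset_index(drop=True)
        df["label"] = df["label"].astype(np.int64)
        if (df["label"] < 0).any():
            raise ValueError("tissue labels must be non-negative")
        if df["label"].duplicated().any():
            dup = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate tissue labels: {dup}")
        if df["tissue"].duplicated().any():
            dup = df.loc[df["tissue"].duplicated(), "tissue"].tolist()
            raise ValueError(f"duplicate tissue names: {dup}")
        bg = df[df["label"] == BACKGROUND_LABEL]
        if len(bg) != 1:
            raise ValueError("exactly one background row (label 0) required")
        if bg["sigma_S_per_m"].iloc[0] != 0 or bg["rho_kg_per_m3"].iloc[0] != 0:
            raise ValueError("background row must have sigma = 0 and rho = 0")
        tissue = df[df["label"] != BACKGROUND_LABEL]
        if (tissue["sigma_S_per_m"] < 0).any():
            raise ValueError("tissue conductivity must be >= 0")
        if (tissue["eps_r"] < 1).any():
            raise ValueError("tissue relative permittivity must be >= 1")
        if (tissue["rho_kg_per_m3"] <= 0).any():
            raise ValueError("tissue density must be > 0")
        object.__setattr__(self, "frame", df)

    # -- convenience accessors -------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def tissues(self) -> list[str]:
        return self.frame["tissue"].tolist()

    def row(self, tissue: str) -> pd.Series:
        sel = self.frame[self.frame["tissue"] == tissue]
        if sel.empty:
            raise KeyError(f"tissue {tissue!r} not in table")
        return sel.iloc[0]

    def label_of(self, tissue: str) -> int:
        return int(self.row(tissue)["label"])

    def name_of(self, label: int) -> str:
        sel = self.frame[self.frame["label"] == label]
        if sel.empty:
            raise KeyError(f"label {label} not in table")
        return str(sel["tissue"].iloc[0])

    def lookup_arrays(self, what: str, max_label: int | None = None) -> np.ndarray:
        """Dense label -> property lookup array (index = label).

        Entries for labels absent from the table are 0 (background-like);
        validity against a phantom is checked by :func:`read_phantom` /
        :func:`validate_phantom_labels`.
        """
        if max_label is None:
            max_label = int(self.frame["label"].max())
        out = np.zeros(max_label + 1, dtype=np.float64)
        lab = self.frame["label"].to_numpy()
        out[lab[lab <= max_label]] = self.frame[what].to_numpy()[lab <= max_label]
        return out

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_rows(
        cls, rows: Sequence[tuple[str, int, float, float, float]]
    ) -> "TissuePropertyTable":
        return cls(pd.DataFrame(rows, columns=list(PROPERTY_COLUMNS)))


def read_property_table(path: str | Path) -> TissuePropertyTable:
    """Read a tissue property table from a header CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # usecols tolerates annotation columns (e.g. a "source" column) in
    # packaged tables
    df = pd.read_csv(path, usecols=list(PROPERTY_COLUMNS))
    return TissuePropertyTable(df)


# ---------------------------------------------------------------------------
# Voxel phantom
# ---------------------------------------------------------------------------


@dataclass
class VoxelPhantom:
    """Labelled 3-D tissue grid with geometry metadata.

    Parameters
    ----------
    labels
        Integer grid; 0 is background (air).
    voxel_size
        Edge length of the (isotropic) cubic voxel in metres.
    origin
        Position in metres of the corner of voxel (0, 0, 0) in the body
        frame, per axis.
    head_mask
        Boolean grid of the same shape marking head voxels; must be a
        subset of the tissue voxels.
    long_axis
        Grid axis aligned with the body's superior-inferior direction.
    alignment_z
        Body-frame coordinate (metres, along ``long_axis``) of the plane
        aligned to the coil centre in the standard position -- the central
        heart level.
    """

    labels: np.ndarray
    voxel_size: float = 0.002
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    head_mask: np.ndarray | None = None
    long_axis: int = 2
    alignment_z: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.long_axis not in (0, 1, 2):
            raise ValueError("long_axis must be 0, 1 or 2")
        if self.head_mask is None:
            self.head_mask = np.zeros(self.labels.shape, dtype=bool)
        self.head_mask = np.ascontiguousarray(self.head_mask.astype(bool))
        if self.head_mask.shape != self.labels.shape:
            raise ValueError("head mask shape must match the label grid")
        if (self.head_mask & (self.labels == BACKGROUND_LABEL)).any():
            raise ValueError("head mask must be a subset of tissue voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND_LABEL

    def voxel_centres(self) -> np.ndarray:
        """(n_voxel, 3) body-frame centre positions of all voxels, C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return np.asarray(self.origin) + (idx + 0.5) * self.voxel_size


def validate_phantom_labels(
    phantom: VoxelPhantom, props: TissuePropertyTable
) -> None:
    """Raise if the volume contains a label missing from the table."""
    present = np.unique(phantom.labels)
    known = set(int(x) for x in props.labels)
    unknown = [int(x) for x in present if int(x) not in known]
    if unknown:
        raise ValueError(f"labels in volume absent from property table: {unknown}")


# -- phantom I/O: raw volume + JSON sidecar ----------------------------------


def write_phantom(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Write a phantom as ``<path>.raw`` + ``<path>.mask.raw`` + ``<path>.json``.

    The raw files hold the little-endian int16 label volume and the uint8
    head-mask plane in C order; the JSON sidecar is the source of truth for
    shape and geometry.  Returns the sidecar path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raw = path.with_suffix(".raw")
    mask_raw = path.with_suffix(".mask.raw")
    sidecar = path.with_suffix(".json")
    phantom.labels.astype("<i2").tofile(raw)
    phantom.head_mask.astype(np.uint8).tofile(mask_raw)
    meta = {
        "format": "rfdosim-phantom-v1",
        "shape": list(phantom.shape),
        "dtype": "<i2",
        "order": "C",
        "voxel_size_m": phantom.voxel_size,
        "origin_m": list(phantom.origin),
        "long_axis": phantom.long_axis,
        "alignment_z_m": phantom.alignment_z,
        "volume_file": raw.name,
        "head_mask_file": mask_raw.name,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_phantom(
    path: str | Path, table_path: str | Path
) -> tuple[VoxelPhantom, TissuePropertyTable]:
    """Read a phantom (sidecar path or basename) and its property table.

    Validates that every nonzero label in the volume has a table row.
    """
    path = Path(path)
    sidecar = path if path.suffix == ".json" else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    voxel_size = float(meta["voxel_size_m"])
    if voxel_size <= 0:
        raise ValueError("non-positive voxel size in sidecar")
    labels = np.fromfile(sidecar.parent / meta["volume_file"], dtype=meta["dtype"])
    labels = labels.reshape(shape).astype(np.int16)
    mask = np.fromfile(
        sidecar.parent / meta["head_mask_file"], dtype=np.uint8
    ).reshape(shape).astype(bool)
    phantom = VoxelPhantom(
        labels=labels,
        voxel_size=voxel_size,
        origin=tuple(meta["origin_m"]),
        head_mask=mask,
        long_axis=int(meta["long_axis"]),
        alignment_z=float(meta["alignment_z_m"]),
    )
    props = read_property_table(table_path)
    validate_phantom_labels(phantom, props)
    return phantom, props


def export_nifti(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Optional NIfTI export of the label volume for viewer interoperability."""
    import nibabel as nib

    affine = np.diag([phantom.voxel_size * 1000.0] * 3 + [1.0])  # mm for NIfTI
    affine[:3, 3] = np.asarray(phantom.origin) * 1000.0
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    path = Path(path)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Mass accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueMassTable:
    """Per-tissue (or per-group) masses in kg."""

    masses: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, m in self.masses.items():
            if m < 0:
                raise ValueError(f"negative mass for {name!r}")
        object.__setattr__(self, "masses", dict(self.masses))

    @property
    def total(self) -> float:
        return float(sum(self.masses.values()))

    def __getitem__(self, tissue: str) -> float:
        return self.masses[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.masses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tissue": list(self.masses), "mass_kg": list(self.masses.values())}
        )


def tissue_masses(
    phantom: VoxelPhantom, props: TissuePropertyTable
) -> TissueMassTable:
    """Mass of every tissue: voxel count x voxel volume x density.

    Background carries zero mass and is omitted from the result.
    """
    validate_phantom_labels(phantom, props)
    counts = np.bincount(
        phantom.labels.ravel(), minlength=int(props.labels.max()) + 1
    )
    out: dict[str, float] = {}
    for _, row in props.frame.iterrows():
        lab = int(row["label"])
        if lab == BACKGROUND_LABEL:
            continue
        out[str(row["tissue"])] = (
            float(counts[lab]) * phantom.voxel_volume * float(row["rho_kg_per_m3"])
        )
    return TissueMassTable(out)


# ---------------------------------------------------------------------------
# Homogenization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueGroupMap:
    """Mapping from detailed tissue name to homogenized group name."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, tissue: str) -> str:
        return self.mapping[tissue]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.mapping.items() if g == group]


def homogenize_dielectrics(
    masses: TissueMassTable,
    props: TissuePropertyTable,
    groups: TissueGroupMap,
) -> TissuePropertyTable:
    """Mass-weighted homogenization of dielectric properties per group.

    The homogenized complex permittivity of a group is the mass-weighted
    mean of its constituents'; since the weighting is linear, conductivity
    and relative permittivity are each the mass-weighted mean:

        sigma_hom = sum_i sigma_i m_i / sum_i m_i
        eps_hom   = sum_i eps_i   m_i / sum_i m_i

    Group density is also mass-weighted, which preserves total mass exactly
    when voxel counts are preserved.  Labels of the output rows are assigned
    1..n_groups in group order, with the background row kept as label 0.
    """
    rows: list[tuple[str, int, float, float, float]] = [
        ("Background", BACKGROUND_LABEL, 0.0, 1.0, 0.0)
    ]
    for i, group in enumerate(groups.groups, start=1):
        members = groups.members(group)
        m = np.array([masses[t] if t in masses else 0.0 for t in members])
        if m.sum() <= 0:
            raise ValueError(f"group {group!r} has zero total mass")
        sig = np.array([props.row(t)["sigma_S_per_m"] for t in members])
        eps = np.array([props.row(t)["eps_r"] for t in members])
        rho = np.array([props.row(t)["rho_kg_per_m3"] for t in members])
        w = m / m.sum()
        rows.append(
            (group, i, float(w @ sig), float(w @ eps), float(w @ rho))
        )
    return TissuePropertyTable.from_rows(rows)


def group_masses(masses: TissueMassTable, groups: TissueGroupMap) -> TissueMassTable:
    """Aggregate a detailed mass table to group level (mass conserving)."""
    out: dict[str, float] = {}
    for tissue, m in masses.masses.items():
        out[groups[tissue]] = out.get(groups[tissue], 0.0) + m
    return TissueMassTable(out)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

TOTAL_ROW = "Total weight"


@dataclass(frozen=True)
class ModelComparison:
    """Reference-vs-individual comparison table.

    One row per compared tissue plus a total-weight row, with masses in kg,
    weight deviation in % of the reference mass, and Dice overlap in %
    where both phantoms were supplied on a common grid.
    """

    frame: pd.DataFrame

    def deviation(self, tissue: str) -> float:
        sel = self.frame[self.frame["tissue"] == tissue]
        if sel.empty:
            raise KeyError(tissue)
        return float(sel["weight_deviation_pct"].iloc[0])

    def dice(self, tissue: str) -> float:
        sel = self.frame[self.frame["tissue"] == tissue]
        if sel.empty:
            raise KeyError(tissue)
        return float(sel["dice_pct"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def dice_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Dice overlap 2|X n Y| / (|X| + |Y|) x 100 of two boolean voxel sets.

    Defined as 0 % when both sets are empty.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("voxel sets must share a common grid")
    nx = int(x.sum())
    ny = int(y.sum())
    if nx + ny == 0:
        return 0.0
    inter = int((x & y).sum())
    return 200.0 * inter / (nx + ny)


def weight_deviation_pct(reference: float, individual: float) -> float:
    """Deviation convention: (individual - reference) / reference x 100."""
    if reference == 0:
        raise ZeroDivisionError("reference mass is zero")
    return (individual - reference) / reference * 100.0


def compare_models(
    ref_masses: TissueMassTable,
    ind_masses: TissueMassTable,
    ref_phantom: VoxelPhantom | None = None,
    ind_phantom: VoxelPhantom | None = None,
    ref_props: TissuePropertyTable | None = None,
    ind_props: TissuePropertyTable | None = None,
    tissues: Sequence[str] | None = None,
) -> ModelComparison:
    """Tabulate per-tissue mass deviation (and Dice when geometry is given).

    ``tissues`` restricts and orders the compared rows; by default the keys
    shared by both mass tables are compared.  Dice is computed only when
    both phantoms (and their tables, for label lookup) are supplied on
    matching grids.
    """
    if tissues is None:
        tissues = [t for t in ref_masses.masses if t in ind_masses]
    else:
        for t in tissues:
            if t not in ref_masses or t not in ind_masses:
                raise KeyError(f"tissue {t!r} missing from a mass table")

    with_dice = ref_phantom is not None and ind_phantom is not None
    if with_dice:
        assert ref_phantom is not None and ind_phantom is not None
        if ref_phantom.shape != ind_phantom.shape:
            raise ValueError("Dice requested on mismatched grids")
        if ref_props is None or ind_props is None:
            raise ValueError("Dice requires both property tables for label lookup")

    records = []
    for t in tissues:
        dice = np.nan
        if with_dice:
            try:
                ref_lab = ref_props.label_of(t)  # type: ignore[union-attr]
                ind_lab = ind_props.label_of(t)  # type: ignore[union-attr]
            except KeyError:
                dice = np.nan
            else:
                dice = dice_coefficient(
                    ref_phantom.labels == ref_lab,  # type: ignore[union-attr]
                    ind_phantom.labels == ind_lab,  # type: ignore[union-attr]
                )
        records.append(
            {
                "tissue": t,
                "reference_mass_kg": ref_masses[t],
                "individual_mass_kg": ind_masses[t],
                "weight_deviation_pct": weight_deviation_pct(
                    ref_masses[t], ind_masses[t]
                ),
                "dice_pct": dice,
            }
        )
    records.append(
        {
            "tissue": TOTAL_ROW,
            "reference_mass_kg": ref_masses.total,
            "individual_mass_kg": ind_masses.total,
            "weight_deviation_pct": weight_deviation_pct(
                ref_masses.total, ind_masses.total
            ),
            "dice_pct": np.nan,
        }
    )
    return ModelComparison(pd.DataFrame.from_records(records))
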