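"""Compound data model and I/O.

A :class:`CompoundSet` holds, in aligned row order, the compound records
(identifier, V_ss in L/kg, f_u as a fraction, optional RDKit molecule) and an
``n x p`` numeric descriptor matrix.  V_ss is always modeled as log10(V_ss);
f_u may be missing and carries an explicit missing mask so that mean-imputed
compounds can be tracked through splitting and classification.

Class assignment follows the anatomical-volume rationale: class 1 is V_ss up
to the extracellular fluid volume (0.3 L/kg), class 2 is 0.3–1 L/kg (tissue
distribution), class 3 is above 1 L/kg (extensive cellular binding).  Two
boundary conventions at exactly 1 L/kg are in circulation (class 2 vs class 3);
:class:`ClassScheme` makes the choice explicit.  The six-class scheme further
splits each V_ss class at f_u = 0.7 into high-f_u ("a") and low/intermediate
("b") halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CompoundSet",
    "ClassScheme",
    "read_sdf_dataset",
    "write_sdf_dataset",
    "read_descriptor_table",
    "attach_descriptors",
    "assign_vss_class",
    "assign_joint_class",
    "impute_missing_fu",
    "split_cluster_stratified",
]


@dataclass
class CompoundRecord:
    """One compound: identifier, responses and an optional structure handle.

    ``vss`` is the volume of distribution at steady state in L/kg (> 0);
    ``fu`` the fraction unbound in plasma, in (0, 1], or ``None`` if missing.
    """

    compound_id: str
    vss: float
    fu: float | None = None
    name: str | None = None
    structure_ref: object | None = None  # RDKit Mol, or None

    def __post_init__(self) -> None:
        if not np.isfinite(self.vss) or self.vss <= 0:
            raise ValueError(f"{self.compound_id}: vss must be positive, got {self.vss}")
        if self.fu is not None:
            if not np.isfinite(self.fu) or not (0 < self.fu <= 1):
                raise ValueError(f"{self.compound_id}: fu must be in (0, 1], got {self.fu}")


@dataclass
class CompoundSet:
    """Aligned compound records and descriptor matrix."""

    records: list[CompoundRecord]
    descriptors: np.ndarray  # (n, p) float, NaN = missing cell
    descriptor_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.ndim != 2:
            self.descriptors = self.descriptors.reshape(len(self.records), -1)
        n, p = self.descriptors.shape
        if n != len(self.records):
            raise ValueError(f"descriptor rows ({n}) != records ({len(self.records)})")
        if p != len(self.descriptor_names):
            raise ValueError("descriptor_names length does not match matrix width")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("descriptor names must be unique")
        for j, name in enumerate(self.descriptor_names):
            if p and n and np.all(np.isnan(self.descriptors[:, j])):
                raise ValueError(f"descriptor column {name!r} is entirely missing")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def vss(self) -> np.ndarray:
        return np.array([r.vss for r in self.records], dtype=float)

    @property
    def log_vss(self) -> np.ndarray:
        return np.log10(self.vss)

    @property
    def fu(self) -> np.ndarray:
        """f_u values with NaN at missing entries."""
        return np.array([np.nan if r.fu is None else r.fu for r in self.records], dtype=float)

    @property
    def fu_missing_mask(self) -> np.ndarray:
        return np.array([r.fu is None for r in self.records], dtype=bool)

    def subset(self, indices: Sequence[int]) -> "CompoundSet":
        idx = np.asarray(indices, dtype=int)
        return CompoundSet(
            records=[self.records[i] for i in idx],
            descriptors=self.descriptors[idx],
            descriptor_names=list(self.descriptor_names),
            meta=dict(self.meta),
        )

    def select_descriptors(self, names: Sequence[str]) -> "CompoundSet":
        pos = {n: j for j, n in enumerate(self.descriptor_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown descriptors: {missing}")
        cols = [pos[n] for n in names]
        return CompoundSet(
            records=list(self.records),
            descriptors=self.descriptors[:, cols],
            descriptor_names=list(names),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.descriptors, columns=self.descriptor_names, index=self.ids)
        df.insert(0, "vss", self.vss)
        df.insert(1, "fu", self.fu)
        return df


@dataclass(frozen=True)
class ClassScheme:
    """Class boundaries for the 3- and 6-class schemes.

    ``vss_upper_inclusive=True`` assigns V_ss exactly 1 L/kg to class 3
    (">= 1 L/kg" convention); ``False`` keeps it in class 2 ("> 1 L/kg"
    convention).  f_u exactly at the cutoff goes to the low ("b") side.
    """

    vss_boundaries: tuple[float, float] = (0.3, 1.0)
    vss_upper_inclusive: bool = False
    fu_cutoff: float = 0.7
    n_classes: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.vss_boundaries
        if not lo < hi:
            raise ValueError("vss boundaries must be strictly increasing")
        if not (0 < self.fu_cutoff < 1):
            raise ValueError("fu_cutoff must be in (0, 1)")
        if self.n_classes not in (3, 6):
            raise ValueError("n_classes must be 3 or 6")


def assign_vss_class(vss, scheme: ClassScheme = ClassScheme()):
    """Assign the 3-level V_ss class (1, 2 or 3); accepts scalars or arrays."""
    v = np.asarray(vss, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("vss must be positive and finite")
    lo, hi = scheme.vss_boundaries
    out = np.full(v.shape, 2, dtype=int)
    out[v <= lo] = 1
    if scheme.vss_upper_inclusive:
        out[v >= hi] = 3
    else:
        out[v > hi] = 3
    return out.item() if np.isscalar(vss) or out.ndim == 0 else out


def assign_joint_class(vss, fu, scheme: ClassScheme = ClassScheme()):
    """Assign the 6-level V_ss & f_u class ("1a".."3b").

    Suffix "a" means high fraction unbound (f_u > cutoff); "b" low to
    intermediate (f_u <= cutoff).  Missing f_u must be imputed first.
    """
    v = np.atleast_1d(np.asarray(vss, dtype=float))
    f = np.atleast_1d(np.asarray(fu, dtype=float))
    if np.any(np.isnan(f)):
        raise ValueError("fu missing; impute before joint class assignment")
    base = np.atleast_1d(assign_vss_class(v, scheme))
    suffix = np.where(f > scheme.fu_cutoff, "a", "b")
    labels = np.array([f"{b}{s}" for b, s in zip(base, suffix)])
    return labels[0] if np.isscalar(vss) else labels


# ---------------------------------------------------------------------------
# SDF and table I/O
# ---------------------------------------------------------------------------


def _parse_float(mol: Chem.Mol, tag: str) -> float | None:
    if not mol.HasProp(tag):
        return None
    raw = mol.GetProp(tag).strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"tag {tag!r} is non-numeric: {raw!r}")


def read_sdf_dataset(
    path: str | Path,
    vss_field: str = "Vss",
    fu_field: str = "fu",
    descriptor_fields: Sequence[str] | None = None,
) -> CompoundSet:
    """Read compounds from an SDF file with V_ss / f_u data tags.

    One record per SDF entry, in file order.  Records whose structure block
    fails to parse are skipped with a warning (count kept in ``meta``).  A
    missing or blank f_u tag sets the missing mask; a missing V_ss tag on a
    retained record is an error.  Optional ``descriptor_fields`` pulls numeric
    tags into the descriptor matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"no records in {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    records: list[CompoundRecord] = []
    desc_rows: list[list[float]] = []
    n_skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.warning("skipping malformed SDF record %d in %s", i, path.name)
            continue
        cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not cid:
            cid = f"record_{i}"
        vss = _parse_float(mol, vss_field)
        if vss is None:
            raise ValueError(f"record {cid!r}: required tag {vss_field!r} absent or blank")
        fu = _parse_float(mol, fu_field)
        records.append(CompoundRecord(compound_id=cid, vss=vss, fu=fu, structure_ref=mol))
        if descriptor_fields:
            row = []
            for tag in descriptor_fields:
                val = _parse_float(mol, tag)
                row.append(np.nan if val is None else val)
            desc_rows.append(row)
    if not records:
        raise ValueError(f"no records in {path}")
    if descriptor_fields:
        descriptors = np.asarray(desc_rows, dtype=float)
        names = list(descriptor_fields)
    else:
        descriptors = np.empty((len(records), 0))
        names = []
    return CompoundSet(records, descriptors, names, meta={"n_skipped": n_skipped, "source": str(path)})


def write_sdf_dataset(
    cset: CompoundSet,
    path: str | Path,
    vss_field: str = "Vss",
    fu_field: str = "fu",
    write_descriptors: bool = False,
) -> None:
    """Write a CompoundSet to SDF; compounds without a structure get a dummy atom."""
    writer = Chem.SDWriter(str(path))
    try:
        for i, rec in enumerate(cset.records):
            mol = rec.structure_ref if rec.structure_ref is not None else Chem.MolFromSmiles("C")
            mol = Chem.Mol(mol)
            mol.SetProp("_Name", rec.compound_id)
            mol.SetProp(vss_field, repr(float(rec.vss)))
            if rec.fu is not None:
                mol.SetProp(fu_field, repr(float(rec.fu)))
            if write_descriptors:
                for j, name in enumerate(cset.descriptor_names):
                    val = cset.descriptors[i, j]
                    if np.isfinite(val):
                        mol.SetProp(name, repr(float(val)))
            writer.write(mol)
    finally:
        writer.close()


def read_descriptor_table(path: str | Path, id_column: str) -> pd.DataFrame:
    """Read a delimited descriptor table into a numeric DataFrame indexed by id.

    Non-numeric cells become NaN; columns containing missing values are listed
    in ``df.attrs['columns_with_missing']``.  Duplicate ids or a table with no
    numeric column are errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise KeyError(f"id column {id_column!r} not in header")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate ids: {dup}")
    num = df.drop(columns=[id_column]).apply(pd.to_numeric, errors="coerce")
    num = num.loc[:, num.notna().any(axis=0)]
    if num.shape[1] == 0:
        raise ValueError("no numeric descriptor columns")
    num.index = pd.Index(ids, name=id_column)
    missing_cols = [c for c in num.columns if num[c].isna().any()]
    if missing_cols:
        logger.warning("columns with missing values: %s", missing_cols)
    num.attrs["columns_with_missing"] = missing_cols
    return num


def attach_descriptors(cset: CompoundSet, table: pd.DataFrame) -> CompoundSet:
    """Join a descriptor table onto a CompoundSet by compound id."""
    ids = cset.ids
    unmatched = sorted(set(ids) - set(table.index.astype(str)))
    if unmatched:
        raise ValueError(f"ids missing from descriptor table: {unmatched}")
    mat = table.loc[ids].to_numpy(dtype=float)
    return CompoundSet(
        records=list(cset.records),
        descriptors=mat,
        descriptor_names=[str(c) for c in table.columns],
        meta=dict(cset.meta),
    )


# ---------------------------------------------------------------------------
# Missing f_u and splitting
# ---------------------------------------------------------------------------


def impute_missing_fu(cset: CompoundSet) -> CompoundSet:
    """Replace missing f_u by the mean of observed f_u values.

    The missing mask is preserved in ``meta['fu_imputed_ids']`` so imputed
    compounds can be distributed evenly between training and test sets.
    """
    fu = cset.fu
    observed = fu[~np.isnan(fu)]
    if observed.size == 0:
        raise ValueError("all fu values missing; nothing to impute from")
    mean_fu = float(observed.mean())
    new_records = []
    imputed_ids = []
    for rec in cset.records:
        if rec.fu is None:
            new_records.append(replace(rec, fu=mean_fu))
            imputed_ids.append(rec.compound_id)
        else:
            new_records.append(rec)
    meta = dict(cset.meta)
    meta["fu_imputed_ids"] = imputed_ids
    meta["fu_imputed_value"] = mean_fu
    return CompoundSet(new_records, cset.descriptors.copy(), list(cset.descriptor_names), meta)


def _cluster_labels(cset: CompoundSet, cut_height: float | None, n_clusters: int | None) -> np.ndarray:
    """Cluster compounds by similarity.

    With structures present, uses Tanimoto distance on hashed path
    fingerprints; otherwise average-linkage on standardized descriptors.
    """
    n = len(cset)
    have_structures = all(r.structure_ref is not None for r in cset.records)
    if have_structures:
        from pkqspr.domain import compute_fingerprints, tanimoto_distance_matrix

        fps = compute_fingerprints(cset, n_bits=1024)
        dist = tanimoto_distance_matrix(fps)
        condensed = dist[np.triu_indices(n, k=1)]
        default_cut = 0.7
    else:
        X = np.nan_to_num(cset.descriptors, nan=0.0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - X.mean(axis=0)) / sd
        condensed = pdist(Z)
        default_cut = None
    link = linkage(condensed, method="average")
    if n_clusters is not None:
        return fcluster(link, t=n_clusters, criterion="maxclust")
    if cut_height is None:
        if default_cut is None:
            return fcluster(link, t=max(2, int(round(np.sqrt(n)))), criterion="maxclust")
        cut_height = default_cut
    return fcluster(link, t=cut_height, criterion="distance")


def split_cluster_stratified(
    cset: CompoundSet,
    test_fraction: float,
    seed: int,
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> tuple[CompoundSet, CompoundSet]:
    """Cluster-stratified train/test split.

    Compounds are clustered by structural similarity and each cluster
    contributes members to both sets where its size permits, so that the test
    set stays inside the chemical space of the training set.  Compounds whose
    f_u was imputed (per ``meta['fu_imputed_ids']`` or the missing mask) are
    distributed approximately equally by splitting them as a separate stratum
    within each cluster.  Deterministic for a fixed seed.
    """
    n = len(cset)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = _cluster_labels(cset, cut_height, n_clusters)

    imputed = set(cset.meta.get("fu_imputed_ids", []))
    is_imputed = np.array([r.compound_id in imputed for r in cset.records]) | cset.fu_missing_mask

    # strata: (cluster, imputed?) cells; per-cell quotas by largest remainder
    cells: list[np.ndarray] = []
    for lab in np.unique(labels):
        for flag in (False, True):
            idx = np.where((labels == lab) & (is_imputed == flag))[0]
            if idx.size:
                cells.append(idx)
    n_test_total = int(round(test_fraction * n))
    n_test_total = min(max(n_test_total, 1), n - 1)
    quotas = np.array([test_fraction * len(c) for c in cells])
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = n_test_total - base.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        for k in order[:short]:
            base[k] += 1
    elif short < 0:
        order = np.argsort(remainder, kind="stable")
        give = -short
        for k in order:
            if give == 0:
                break
            if base[k] > 0:
                base[k] -= 1
                give -= 1

    test_idx: list[int] = []
    for cell, k in zip(cells, base):
        k = min(k, len(cell))
        perm = rng.permutation(cell)
        test_idx.extend(perm[:k].tolist())

    # guarantee every cluster of size >= 2 appears in both sets
    test_set = set(test_idx)
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size < 2:
            continue
        in_test = [i for i in members if i in test_set]
        if len(in_test) == 0:
            test_set.add(int(rng.choice(members)))
        elif len(in_test) == len(members):
            test_set.discard(int(rng.choice(np.array(in_test))))
    test_idx = sorted(test_set)
    train_idx = [i for i in range(n) if i not in test_set]
    if not train_idx or not test_idx:
        raise ValueError("degenerate split: one side is empty")
    train, test = cset.subset(train_idx), cset.subset(test_idx)
    train.meta["cluster_labels"] = labels[train_idx].tolist()
    test.meta["cluster_labels"] = labels[test_idx].tolist()
    return train, test
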