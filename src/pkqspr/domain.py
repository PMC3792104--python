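"""Fingerprint-distance applicability domain (AD).

A prediction is only trusted for query compounds structurally close to the
training set.  The domain threshold is derived from the training-set distance
distribution: compute all pairwise Euclidean distances between training
fingerprints, keep the distances strictly below their overall mean, and take
mean <d> and sample standard deviation sigma of that restricted set.  Then

    AD = <d> + Z * sigma

with Z (default 0.7) controlling the significance level.  A query compound is
in-domain iff the Euclidean distance to its nearest training neighbor is at
most AD.  On bit vectors the Euclidean distance equals sqrt(Hamming distance).

Fingerprints are hashed linear-path (Daylight-style) bit vectors from RDKit;
length is configurable (32 bits mirrors the original small fingerprint, 1024
is recommended for real use).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ADModel",
    "compute_fingerprints",
    "tanimoto_distance_matrix",
    "ad_stats",
    "ad_threshold",
    "in_domain",
    "coverage_accuracy_sweep",
]


def _mols_from(source) -> list[Chem.Mol]:
    from pkqspr.dataset import CompoundSet

    if isinstance(source, CompoundSet):
        mols = [r.structure_ref for r in source.records]
        if any(m is None for m in mols):
            raise ValueError("CompoundSet has records without structures")
        return mols
    return list(source)


def compute_fingerprints(source, n_bits: int = 32, min_path: int = 1, max_path: int = 7) -> np.ndarray:
    """Hashed linear-path fingerprints as an (n, n_bits) boolean array.

    ``source`` is a CompoundSet with structures or an iterable of RDKit Mols.
    Deterministic per molecule.
    """
    mols = _mols_from(source)
    out = np.zeros((len(mols), n_bits), dtype=bool)
    for i, mol in enumerate(mols):
        if mol is None:
            raise ValueError(f"molecule {i} is unparseable")
        fp = Chem.RDKFingerprint(mol, minPath=min_path, maxPath=max_path, fpSize=n_bits, branchedPaths=False)
        out[i] = np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) == ord("1")
    return out


def euclidean_bit_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance between bit-vector sets (= sqrt Hamming)."""
    return cdist(np.asarray(a, dtype=float), np.asarray(b, dtype=float), metric="euclidean")


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Square Tanimoto (Jaccard) distance matrix for bit-vector fingerprints."""
    F = np.asarray(fps, dtype=float)
    inter = F @ F.T
    ones = F.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return 1.0 - sim


@dataclass
class ADModel:
    training_fingerprints: np.ndarray
    overall_mean: float
    d_bar: float
    sigma: float
    z: float
    threshold: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "training_fingerprints": self.training_fingerprints.astype(int).tolist(),
            "overall_mean": self.overall_mean,
            "d_bar": self.d_bar,
            "sigma": self.sigma,
            "z": self.z,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ADModel":
        d = json.loads(Path(path).read_text())
        return cls(
            training_fingerprints=np.asarray(d["training_fingerprints"], dtype=bool),
            overall_mean=d["overall_mean"],
            d_bar=d["d_bar"],
            sigma=d["sigma"],
            z=d["z"],
            threshold=d["threshold"],
        )


def ad_stats(distances: Sequence[float], z: float) -> dict:
    """AD statistics from a flat collection of pairwise distances.

    Restricts to distances *strictly* below the overall mean, then
    AD = <d> + z * sigma with sigma the sample (n-1) standard deviation.  If
    every distance equals the mean (restricted set empty), AD falls back to
    the overall mean with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    overall = float(d.mean())
    restricted = d[d < overall]
    if restricted.size == 0:
        logger.warning("all pairwise distances equal; AD set to the overall mean")
        return {"overall_mean": overall, "d_bar": overall, "sigma": 0.0, "threshold": overall}
    d_bar = float(restricted.mean())
    sigma = float(restricted.std(ddof=1)) if restricted.size > 1 else 0.0
    return {"overall_mean": overall, "d_bar": d_bar, "sigma": sigma, "threshold": d_bar + z * sigma}


def ad_threshold(training_fingerprints: np.ndarray, z: float = 0.7) -> ADModel:
    """Fit the applicability domain from training fingerprints."""
    fps = np.asarray(training_fingerprints)
    if fps.shape[0] < 3:
        raise ValueError("need at least 3 training compounds")
    dists = pdist(fps.astype(float), metric="euclidean")
    s = ad_stats(dists, z)
    return ADModel(
        training_fingerprints=fps,
        overall_mean=s["overall_mean"],
        d_bar=s["d_bar"],
        sigma=s["sigma"],
        z=z,
        threshold=s["threshold"],
    )


def in_domain(
    model: ADModel,
    query_fingerprints: np.ndarray,
    training_fingerprints: np.ndarray | None = None,
    k: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """In-domain flags and nearest-neighbor distances for query compounds.

    A query is in-domain iff the mean Euclidean distance to its ``k`` nearest
    training neighbors (default 1) is at most the AD threshold.
    """
    train = model.training_fingerprints if training_fingerprints is None else training_fingerprints
    D = euclidean_bit_distance(query_fingerprints, train)
    k = min(k, D.shape[1])
    nearest = np.sort(D, axis=1)[:, :k].mean(axis=1)
    return nearest <= model.threshold, nearest


def coverage_accuracy_sweep(
    training_fingerprints: np.ndarray,
    query_fingerprints: np.ndarray,
    z_values: Sequence[float],
    metric: Callable[[np.ndarray], float],
    k: int = 1,
):
    """Coverage and in-domain accuracy as a function of Z.

    ``metric`` receives the boolean in-domain mask over the query set and
    returns the accuracy statistic (Q², AUC, ...) computed on that subset
    (NaN when the subset is too small).  Coverage is the in-domain percentage
    and is monotone non-decreasing in Z.
    """
    import pandas as pd

    z_values = list(z_values)
    if not z_values:
        raise ValueError("empty Z grid")
    rows = []
    for z in z_values:
        model = ad_threshold(training_fingerprints, z=z)
        mask, _ = in_domain(model, query_fingerprints, k=k)
        rows.append(
            {
                "z": z,
                "threshold": model.threshold,
                "coverage_pct": 100.0 * mask.mean(),
                "accuracy": metric(mask),
            }
        )
    return pd.DataFrame(rows)
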