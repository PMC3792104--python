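"""Synthetic QSPR data with known ground truth.

The generator emulates the statistical structure the pipeline assumes rather
than real medicinal-chemistry space: two anti-correlated latent axes — a
lipophilicity-like factor L and a solubility-like factor S, corr(L, S) = -0.5
by default — drive both responses with opposite signs,

    log10 V_ss  =  vss_intercept + a*L − b*S + eps1
    logit(f_u)  =  fu_intercept  − c*L + d*S + eps2          (a, b, c, d > 0)

so lipophilic compounds have high volume of distribution and low fraction
unbound, and soluble ones the reverse.  Descriptors load sparsely on one
factor each (plus pure-noise columns), V_ss is clipped to the observed
0.035–60 L/kg range, and f_u can be masked missing at a configurable rate.
Default intercepts/coefficients put roughly a quarter of compounds in each of
the low and moderate V_ss classes and half above 1 L/kg, with high f_u (> 0.7)
in a small minority — the class imbalance the balanced forest exists for.

Ground truth (factors, loadings, coefficients, expected association signs) is
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from pkqspr.dataset import CompoundRecord, CompoundSet

__all__ = ["GeneratorConfig", "generate_qspr_dataset", "generate_structures", "make_marginal_standin_records"]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator."""

    n: int = 400
    p: int = 30
    rho: float = -0.5  # corr(L, S)
    frac_lipo: float = 0.35  # descriptor columns loading on L
    frac_sol: float = 0.35  # descriptor columns loading on S; rest pure noise
    a: float = 0.4  # logVss coefficient on L
    b: float = 0.4  # logVss coefficient on -S
    c: float = 0.8  # logit(fu) coefficient on -L
    d: float = 0.8  # logit(fu) coefficient on S
    vss_intercept: float = -0.04
    fu_intercept: float = -0.7
    noise_sd: float = 0.3  # descriptor and response noise SD
    fu_link: str = "logit"  # 'logit' keeps fu in (0, 1); 'linear' clips
    missing_fu_rate: float = 0.157
    vss_range: tuple[float, float] = (0.035, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) <= 0:
            raise ValueError("response coefficients a, b, c, d must be positive")
        if not (0 <= self.missing_fu_rate < 1):
            raise ValueError("missing_fu_rate must be in [0, 1)")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        if self.fu_link not in ("logit", "linear"):
            raise ValueError("fu_link must be 'logit' or 'linear'")
        if self.frac_lipo + self.frac_sol > 1:
            raise ValueError("loading fractions exceed 1")


def generate_qspr_dataset(config: GeneratorConfig = GeneratorConfig()) -> tuple[CompoundSet, dict]:
    """Draw a synthetic compound set plus ground truth, deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cov = np.array([[1.0, cfg.rho], [cfg.rho, 1.0]])
    factors = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n)  # columns: L, S
    L, S = factors[:, 0], factors[:, 1]

    n_lipo = int(round(cfg.frac_lipo * cfg.p))
    n_sol = int(round(cfg.frac_sol * cfg.p))
    loadings = np.zeros((cfg.p, 2))
    magnitudes = rng.uniform(0.6, 1.4, size=cfg.p)
    loadings[:n_lipo, 0] = magnitudes[:n_lipo]
    loadings[n_lipo : n_lipo + n_sol, 1] = magnitudes[n_lipo : n_lipo + n_sol]
    X = factors @ loadings.T + rng.normal(0, cfg.noise_sd, size=(cfg.n, cfg.p))

    log_vss = cfg.vss_intercept + cfg.a * L - cfg.b * S + rng.normal(0, cfg.noise_sd, cfg.n)
    vss = np.clip(np.power(10.0, log_vss), *cfg.vss_range)

    eta = cfg.fu_intercept - cfg.c * L + cfg.d * S + rng.normal(0, cfg.noise_sd, cfg.n)
    if cfg.fu_link == "logit":
        fu = 1.0 / (1.0 + np.exp(-eta))
    else:
        fu = np.clip(0.5 + 0.15 * eta, 1e-4, 1.0)
    fu = np.clip(fu, 1e-6, 1.0)

    missing = rng.random(cfg.n) < cfg.missing_fu_rate

    names = (
        [f"lipo_{j:02d}" for j in range(n_lipo)]
        + [f"sol_{j:02d}" for j in range(n_sol)]
        + [f"noise_{j:02d}" for j in range(cfg.p - n_lipo - n_sol)]
    )
    records = [
        CompoundRecord(
            compound_id=f"CPD{i:04d}",
            vss=float(vss[i]),
            fu=None if missing[i] else float(fu[i]),
        )
        for i in range(cfg.n)
    ]
    cset = CompoundSet(records, X, names, meta={"generator_seed": cfg.seed})

    # expected association sign of each informative descriptor with each response:
    # cov(x_j, logVss) = l_jL (a − rho b) − l_jS (b − rho a), etc.
    sign_logvss = np.sign(loadings[:, 0] * (cfg.a - cfg.rho * cfg.b) - loadings[:, 1] * (cfg.b - cfg.rho * cfg.a))
    sign_fu = np.sign(-loadings[:, 0] * (cfg.c - cfg.rho * cfg.d) + loadings[:, 1] * (cfg.d - cfg.rho * cfg.c))
    truth = {
        "factors": factors,
        "loadings": loadings,
        "coefficients": {"a": cfg.a, "b": cfg.b, "c": cfg.c, "d": cfg.d},
        "log_vss_latent": log_vss,
        "fu_latent": fu,
        "informative": np.abs(loadings).sum(axis=1) > 0,
        "sign_logvss": sign_logvss,
        "sign_fu": sign_fu,
        "missing_mask": missing,
        "config": cfg,
    }
    return cset, truth


# ---------------------------------------------------------------------------
# Toy structures for fingerprint / AD tests
# ---------------------------------------------------------------------------

_SUBSTITUENTS = ["", "C", "O", "N", "Cl", "F", "CC", "CO", "C(C)C", "OC"]


def generate_structures(n: int, seed: int = 0, family: str | None = None) -> list[Chem.Mol]:
    """Deterministic toy molecules from two scaffold families.

    Family "alkane": linear/branched alkanes of growing length; family
    "aromatic": substituted benzenes.  With ``family=None`` the two families
    alternate, giving a set whose inter-family fingerprint distances exceed
    intra-family ones (useful for applicability-domain cluster tests).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    smiles: list[str] = []
    k = 0
    while len(smiles) < n:
        fam = family or ("alkane" if k % 2 == 0 else "aromatic")
        sub = _SUBSTITUENTS[rng.integers(0, len(_SUBSTITUENTS))]
        if fam == "alkane":
            length = 3 + (k // 2) % 8
            smi = "C" * length + sub
        else:
            smi = f"c1ccccc1{sub}" if sub else "c1ccccc1"
        if Chem.MolFromSmiles(smi) is not None:
            smiles.append(smi)
        k += 1
    mols = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", f"TOY{i:03d}")
        mols.append(mol)
    return mols


def make_marginal_standin_records(seed: int = 0) -> CompoundSet:
    """Synthetic stand-in compound table mirroring published marginal totals.

    This is *constructed*, not real, data: 642 compounds whose V_ss and f_u
    values are drawn inside class bins so that the 3-class totals are
    167/167/308 under the strict "> 1 L/kg" convention, the 6-class totals
    (with ">= 1" and mean-imputed f_u) are 29/138/39/119/59/258, exactly nine
    compounds sit at V_ss = 1.0 L/kg (reconciling the two conventions), and
    101 of the 642 f_u values are missing.  It exercises the ingestion,
    imputation and class-counting machinery at realistic scale.
    """
    rng = np.random.default_rng(seed)
    # joint cells under the ">= 1" convention: (vss_bin, suffix, count)
    cells = [
        ("low", "a", 29),
        ("low", "b", 138),
        ("mid", "a", 39),
        ("mid", "b", 119),
        ("high", "a", 59),
        ("high", "b", 258),
    ]
    records: list[CompoundRecord] = []
    i = 0
    n_boundary = 9  # compounds at exactly 1.0 L/kg (class 2 vs 3 disagreement)
    boundary_left = n_boundary
    for vbin, suffix, count in cells:
        for _ in range(count):
            if vbin == "low":
                vss = float(rng.uniform(0.035, 0.3))
            elif vbin == "mid":
                vss = float(rng.uniform(0.31, 0.99))
            else:
                if suffix == "b" and boundary_left > 0:
                    vss = 1.0
                    boundary_left -= 1
                else:
                    vss = float(rng.uniform(1.01, 60.0))
            fu = float(rng.uniform(0.75, 1.0)) if suffix == "a" else float(rng.uniform(0.005, 0.65))
            records.append(CompoundRecord(compound_id=f"STD{i:04d}", vss=vss, fu=fu))
            i += 1
    # mask 101 f_u values missing, all in "b" cells so that mean-imputation
    # (observed mean < 0.7) leaves their class unchanged
    b_indices = [j for j, r in enumerate(records) if r.fu is not None and r.fu <= 0.65]
    drop = rng.choice(np.array(b_indices), size=101, replace=False)
    for j in drop:
        records[j].fu = None
    rng.shuffle(records)
    return CompoundSet(records, np.empty((len(records), 0)), [], meta={"standin": True})
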