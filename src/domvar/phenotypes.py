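"""Record editing, censoring penalties and sire-model pre-correction of
fertility phenotypes.

Raw insemination/calving records are first edited on age and trait bounds,
censored records are penalised (+21 days on IFL, +1 on NINS), and a
pedigree-based sire model is fitted to the full recorded population so fixed
effects (herd, year-month, age covariate, parity) are estimated on far more
animals than the genotyped subset.  The pre-corrected phenotype keeps the
genetic and residual parts: ``y_hc = Z_s s + e`` for heifers and
``y_cc = Z_s s + mean_k(e_k)`` over a cow's parities (the permanent
environment effect is excluded).  Cow phenotypes carry reliabilities
``r2 = n h2 / ((n-1) h2 + 1)`` and residual weights ``w = r2/(1-r2)``
standardized to mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grm import RelMatrix, pedigree_a
from .pedigree import Pedigree
from .reml import AIREML

__all__ = [
    "EDIT_RULES",
    "edit_records",
    "apply_censoring_penalty",
    "SireModel",
    "PrecorrectedPhenotypes",
    "precorrect",
    "reliability",
    "residual_weights",
]

# (stage, column, low, high): records kept iff low < value < high
EDIT_RULES = [
    ("heifer", "age_first_insemination", 270.0, 900.0),
    ("heifer", "NINS", None, 8.0),
    ("heifer", "IFL", None, 365.0),
    ("cow", "age_first_calving", 550.0, 1100.0),
    ("cow", "NINS", None, 8.0),
    ("cow", "ICF", None, 230.0),
    ("cow", "IFL", None, 365.0),
]


def edit_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the stage-specific editing bounds.

    Heifers are kept iff 270 < age at first insemination < 900, NINS < 8 and
    IFL < 365; cows iff 550 < age at first calving < 1100, NINS < 8,
    ICF < 230 and IFL < 365 (strict bounds).  Records missing a required
    field are rejected with reason "incomplete".  Returns the retained
    records and a per-rule removal report.
    """
    records = records.copy()
    reasons = pd.Series("", index=records.index, dtype=object)
    for stage, col, low, high in EDIT_RULES:
        in_stage = records["stage"] == stage
        vals = pd.to_numeric(records.loc[in_stage, col], errors="coerce")
        missing = vals.isna()
        fail = pd.Series(False, index=vals.index)
        if low is not None:
            fail |= vals <= low
        if high is not None:
            fail |= vals >= high
        for idx in vals.index[missing & (reasons.loc[vals.index] == "")]:
            reasons.at[idx] = "incomplete"
        for idx in vals.index[fail & ~missing & (reasons.loc[vals.index] == "")]:
            reasons.at[idx] = f"{stage}:{col}"
    kept = records[reasons == ""].reset_index(drop=True)
    report = (
        reasons[reasons != ""]
        .value_counts()
        .rename_axis("rule")
        .reset_index(name="n_removed")
    )
    return kept, report


def apply_censoring_penalty(records: pd.DataFrame) -> pd.DataFrame:
    """Add 21 days to censored IFL and one count to censored NINS."""
    out = records.copy()
    cen = out["censored"].astype(bool)
    out.loc[cen, "IFL"] = out.loc[cen, "IFL"] + 21.0
    out.loc[cen, "NINS"] = out.loc[cen, "NINS"] + 1
    return out


# ------------------------------------------------------------------ sire model
def _dummies(series: pd.Series, drop_first: bool) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(series.astype("category"), drop_first=drop_first, dtype=float)
    return d.to_numpy(), [f"{series.name}[{c}]" for c in d.columns]


class SireModel(BaseEstimator):
    """Pedigree-based sire model for one fertility trait.

    ``y = X b + Z_s s + (Z pe) + e`` with ``s ~ N(0, sigma_s^2 A_s)``,
    cow-stage records additionally carrying a permanent-environment effect
    ``pe ~ N(0, sigma_pe^2 I)`` across parities.  Fixed effects: herd,
    year-month of first insemination, the stage's age covariate (linear) and,
    for cows, parity.  Fitted by :class:`~domvar.reml.AIREML`.

    Attributes after ``fit``: ``variances_``, ``converged_``, ``beta_``,
    ``sire_effects_`` (pd.Series by sire id), ``pe_effects_``,
    ``residuals_`` (aligned with the fitted records), ``records_``.
    """

    def __init__(self, trait: str = "IFL", stage: str = "heifer",
                 max_iter: int = 200, tol: float = 1e-8):
        self.trait = trait
        self.stage = stage
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, records: pd.DataFrame, sire_pedigree: Pedigree | RelMatrix):
        df = records[records["stage"] == self.stage].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no {self.stage} records")
        if df["herd"].nunique() < 1:
            raise ValueError("records carry no herd codes")
        y = df[self.trait].to_numpy(dtype=np.float64)

        age_col = (
            "age_first_insemination" if self.stage == "heifer" else "age_first_calving"
        )
        X_parts = [np.ones((len(df), 1))]
        names = ["intercept"]
        for col in ("herd", "year_month"):
            if df[col].nunique() > 1:
                mat, nm = _dummies(df[col], drop_first=True)
                X_parts.append(mat)
                names += nm
        age = df[age_col].to_numpy(dtype=np.float64)
        X_parts.append((age - age.mean())[:, None])
        names.append(age_col)
        if self.stage == "cow" and df["parity"].nunique() > 1:
            mat, nm = _dummies(df["parity"], drop_first=True)
            X_parts.append(mat)
            names += nm
        X = np.hstack(X_parts)

        sires = df["sire"].astype(str)
        if isinstance(sire_pedigree, Pedigree):
            A_s = pedigree_a(sire_pedigree, sorted(sires.unique()))
        else:
            A_s = sire_pedigree
        sire_index = {str(s): k for k, s in enumerate(A_s.ids)}
        Zs = np.zeros((len(df), A_s.n))
        for i, s in enumerate(sires):
            Zs[i, sire_index[s]] = 1.0
        components = {"sire": Zs @ A_s.values @ Zs.T}
        Zpe = None
        if self.stage == "cow":
            animals = df["animal"].astype(str)
            uniq = animals.unique()
            aidx = {a: k for k, a in enumerate(uniq)}
            Zpe = np.zeros((len(df), len(uniq)))
            for i, a in enumerate(animals):
                Zpe[i, aidx[a]] = 1.0
            components["pe"] = Zpe @ Zpe.T

        est = AIREML(components=components, max_iter=self.max_iter, tol=self.tol)
        est.fit(y, X=X, feature_names=names)

        self.engine_ = est
        self.variances_ = est.variances_
        self.se_ = est.se_
        self.converged_ = est.converged_
        self.beta_ = pd.Series(est.beta_, index=names)
        fitted_fixed = X @ est.beta_
        # BLUPs on the sire scale: s_hat = sigma_s^2 A Z' P y
        Py = est._Py
        s_hat = est.variances_["sire"] * (A_s.values @ (Zs.T @ Py))
        self.sire_effects_ = pd.Series(s_hat, index=[str(s) for s in A_s.ids])
        pe_hat = None
        if Zpe is not None:
            pe_hat = est.variances_["pe"] * (Zpe.T @ Py)
            self.pe_effects_ = pd.Series(pe_hat, index=list(aidx))
        else:
            self.pe_effects_ = None
        resid = y - fitted_fixed - Zs @ s_hat
        if pe_hat is not None:
            resid = resid - Zpe @ pe_hat
        self.residuals_ = resid
        self.fixed_part_ = fitted_fixed
        self.records_ = df
        return self


@dataclass
class PrecorrectedPhenotypes:
    """Per-animal adjusted phenotypes with reliabilities and weights.

    ``table`` columns: animal, y_c, n (parities used), r2, w, w_star.  For
    heifer traits r2/w/w_star are 1 (identity residual covariance).
    """

    table: pd.DataFrame
    stage: str
    trait: str
    h2: float | None = None

    @property
    def y(self) -> np.ndarray:
        return self.table["y_c"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.table["w_star"].to_numpy()


def reliability(h2, n):
    """Reliability of an n-parity mean, ``n h2 / ((n-1) h2 + 1)``."""
    h2 = np.asarray(h2, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if (n < 1).any():
        raise ValueError("parity count must be >= 1")
    if ((h2 <= 0) | (h2 >= 1)).any():
        raise ValueError("heritability must be in (0, 1)")
    out = n * h2 / ((n - 1) * h2 + 1.0)
    return float(out) if out.ndim == 0 else out


def residual_weights(r2):
    """Raw and mean-standardized residual weights from reliabilities.

    ``w = r2 / (1 - r2)``; ``w* = w / mean(w)`` so the residual covariance
    ``sigma_e^2 diag(1/w*)`` keeps ``sigma_e^2`` on the original scale.
    """
    r2 = np.asarray(r2, dtype=np.float64)
    if ((r2 < 0) | (r2 >= 1)).any():
        raise ValueError("reliabilities must lie in [0, 1)")
    w = r2 / (1.0 - r2)
    if w.mean() == 0:
        raise ValueError("all weights zero")
    return w, w / w.mean()


def precorrect(
    fit: SireModel, h2: float | None = None
) -> PrecorrectedPhenotypes:
    """Pre-corrected phenotypes from a fitted sire model.

    Heifers: ``y_hc = y - X b`` (one record per animal).  Cows:
    ``y_cc = s_hat(sire) + mean(e_hat)`` over the animal's parities, with
    reliabilities from ``h2`` and weights standardized to mean one.
    """
    if not getattr(fit, "converged_", False):
        raise RuntimeError("sire model did not converge; refusing to pre-correct")
    df = fit.records_
    if fit.stage == "heifer":
        tab = pd.DataFrame(
            {
                "animal": df["animal"].astype(str),
                "y_c": df[fit.trait].to_numpy() - fit.fixed_part_,
                "n": 1,
                "r2": 1.0,
                "w": 1.0,
                "w_star": 1.0,
            }
        )
        return PrecorrectedPhenotypes(tab, stage="heifer", trait=fit.trait, h2=h2)

    if h2 is None:
        raise ValueError("cow pre-correction requires the trait heritability h2")
    sire_of = df.groupby("animal", sort=False)["sire"].first().astype(str)
    e_mean = pd.Series(fit.residuals_, index=df["animal"].astype(str)).groupby(
        level=0, sort=False
    ).mean()
    n_par = df.groupby("animal", sort=False).size()
    n_par.index = n_par.index.astype(str)
    usable = n_par[n_par >= 1].index
    s_part = fit.sire_effects_.reindex(sire_of[usable]).to_numpy()
    y_cc = s_part + e_mean[usable].to_numpy()
    r2 = reliability(h2, n_par[usable].to_numpy())
    w, w_star = residual_weights(r2)
    tab = pd.DataFrame(
        {
            "animal": usable,
            "y_c": y_cc,
            "n": n_par[usable].to_numpy(),
            "r2": r2,
            "w": w,
            "w_star": w_star,
        }
    ).reset_index(drop=True)
    return PrecorrectedPhenotypes(tab, stage="cow", trait=fit.trait, h2=h2)
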