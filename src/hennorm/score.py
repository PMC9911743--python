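"""Composite daily movement score: correlation PCA on a balanced weekly
subset, projection of all hen-days onto the first principal component.

Because hens do not all contribute the same number of tracked days, the PCA
is fitted on one day per hen and week (the earliest complete day of each
7-day block since the hen's first tracked day) so every hen and week has
equal mass.  All hen-days are then standardized with the *subset* means and
SDs and projected onto PC1; the PC1 sign is anchored so that travelled
vertical distance loads positively (higher score = more movement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .features import VARIABLES


@dataclass
class PCAModel:
    variables: list[str]
    means: np.ndarray       # subset means, per variable
    sds: np.ndarray         # subset SDs, per variable
    loadings: np.ndarray    # (p, p), columns = components, PC1 sign-anchored
    eigenvalues: np.ndarray  # non-increasing, sums to p
    n_retained: int          # components with eigenvalue > 1

    def explained_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def to_yaml(self, path) -> None:
        payload = {
            "variables": list(self.variables),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_retained": int(self.n_retained),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "PCAModel":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(
            variables=list(p["variables"]),
            means=np.asarray(p["means"], float),
            sds=np.asarray(p["sds"], float),
            loadings=np.asarray(p["loadings"], float),
            eigenvalues=np.asarray(p["eigenvalues"], float),
            n_retained=int(p["n_retained"]),
        )


def weekly_subset(daily: pd.DataFrame) -> pd.DataFrame:
    """The earliest complete day of each hen × 7-day block (blocks counted
    from the hen's first tracked day present in ``daily``).

    Days flagged incomplete or before winter-garden availability are not
    eligible.  Hens with no eligible day are dropped with a warning.
    """
    ok = daily
    if "complete" in daily.columns:
        ok = ok[ok["complete"]]
    if "wg_available" in daily.columns:
        ok = ok[ok["wg_available"]]
    dropped = set(daily["hen_id"]) - set(ok["hen_id"])
    if dropped:
        warnings.warn(f"{len(dropped)} hen(s) with no complete day excluded")
    first = ok.groupby("hen_id")["day"].transform("min")
    week = (ok["day"] - first) // 7
    idx = ok.assign(_week=week).groupby(["hen_id", "_week"])["day"].idxmin()
    return ok.loc[idx.to_numpy()].reset_index(drop=True)


def fit_pca(subset: pd.DataFrame, variables: list[str] | None = None) -> PCAModel:
    """Correlation-based PCA of the weekly subset.

    PC1 is oriented so vertical_per_hour loads positively; components with
    eigenvalue > 1 are the retained ones.
    """
    variables = list(variables or VARIABLES)
    missing = [v for v in variables if v not in subset.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    X = subset[variables].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the PCA")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sds) if s == 0 or not np.isfinite(s)]
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    if X.shape[0] < len(variables):
        warnings.warn(
            "fewer rows than variables: correlation matrix is singular; "
            "trailing eigenvalues will be ~0"
        )
    Z = (X - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign anchor: vertical distance loads positively on PC1
    iv = variables.index("vertical_per_hour")
    if evecs[iv, 0] < 0:
        evecs[:, 0] = -evecs[:, 0]
    # deterministic orientation for the remaining components
    for k in range(1, evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return PCAModel(
        variables=variables,
        means=means,
        sds=sds,
        loadings=evecs,
        eigenvalues=evals,
        n_retained=int((evals > 1.0).sum()),
    )


def project_pc1(
    model: PCAModel,
    daily: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    temperature: pd.Series | None = None,
) -> pd.DataFrame:
    """Project hen-days onto PC1, producing the ScoreTable used by all
    downstream models.

    Rows are standardized with the fitting subset's means/SDs (required for
    comparability with the fitted loadings).  Continuous covariates are
    standardized to mean 0 / SD 1 except time, which stays in raw days so
    the model intercept refers to the first day post-transfer.
    """
    missing = [v for v in model.variables if v not in daily.columns]
    if missing:
        raise ValueError(f"missing variables: {missing}")
    ok = daily
    if "complete" in daily.columns:
        ok = ok[ok["complete"]]
    if "wg_available" in daily.columns:
        ok = ok[ok["wg_available"]]
    Z = (ok[model.variables].to_numpy(float) - model.means) / model.sds
    pc1 = Z @ model.loadings[:, 0]
    out = pd.DataFrame(
        {
            "hen_id": ok["hen_id"].to_numpy(),
            "day": ok["day"].to_numpy(),
            "pc1": pc1,
        }
    )
    out["time"] = out["day"].astype(float)
    out["time2"] = out["time"] ** 2
    if temperature is not None:
        zt = (temperature - temperature.mean()) / temperature.std()
        out["temperature"] = out["day"].map(zt)
    if covariates is not None:
        out = out.merge(covariates, left_on="hen_id", right_index=True, how="left")
        for c in ("body_mass", "tracked_days"):
            if c in out.columns:
                s = out[c].std()
                out[c] = (out[c] - out[c].mean()) / s if s > 0 else 0.0
    return out
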