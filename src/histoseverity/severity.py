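"""PCA-based continuous severity scoring of cutout feature vectors.

The model eigendecomposes the feature scatter of a training matrix X
(n cutouts x m features; m = 108 for the default bank) and uses the first
principal component as a one-dimensional severity axis.  Projections of
the training rows onto PC1 are min-max normalized so the score lives on
[0, 1] with 1 = most severe; new cutouts are projected onto the same axis
and clipped into range.

The scatter operated on is the m x m matrix S = W^T W / (n m), with W the
(by default mean-centered) feature matrix — the feature-space reading that
makes the eigenvector equation and the projection step dimensionally
coherent.  The equivalent n x n Gram-matrix route yields the same
projections up to scale.  Centering can be disabled to decompose the raw
second-moment matrix instead; in that regime PC1 largely encodes the
global feature mean and its variance fraction is inflated accordingly.

The sign of an eigenvector is arbitrary.  When per-row ordinal severity
hints (e.g. control < chronic < acute) are supplied, PC1 is oriented so
the raw score increases with them; otherwise the convention is that the
largest-magnitude PC1 loading is positive.

Usage follows the model/results pattern::

    model = SeverityModel(X, ids=ids, labels=levels)
    res = model.fit()
    print(res.summary())
    s = res.score(new_features)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector

__all__ = ["SeverityModel", "SeverityResults", "SeverityScore", "DegenerateFitError"]


class DegenerateFitError(ValueError):
    """Raised when the training features carry no usable variance."""


def _layout_hash(names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SeverityScore:
    """A scored cutout: raw PC1 projection and the [0, 1] normalized score."""

    cutout_id: str
    raw_pc1: float
    score: float
    clipped: bool


class SeverityModel:
    """PCA severity model over a cutout-by-feature training matrix.

    Parameters
    ----------
    features : array-like or DataFrame, shape (n, m)
        Training feature matrix; no missing values, n >= 2.
    ids : sequence of str, optional
        Cutout identifiers (defaults to row numbers; taken from the index
        for DataFrame input).
    labels : sequence of numbers, optional
        Per-row ordinal severity hints used only to orient the PC1 sign.
    center : bool
        Subtract the per-feature training mean before the decomposition
        (default True).  ``center=False`` decomposes the literal
        uncentered second-moment matrix.
    standardize : bool
        Additionally divide by the per-feature training std (default
        False; exploratory option).
    """

    def __init__(
        self,
        features,
        ids: Sequence[str] | None = None,
        labels: Sequence[float] | None = None,
        feature_names: Sequence[str] | None = None,
        center: bool = True,
        standardize: bool = False,
    ):
        if isinstance(features, pd.DataFrame):
            if feature_names is None:
                feature_names = [str(c) for c in features.columns]
            if ids is None:
                ids = [str(i) for i in features.index]
            features = features.to_numpy()
        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 training rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        self.X = X
        self.nobs, self.n_features = n, m
        self.ids = tuple(str(i) for i in ids) if ids is not None else tuple(
            str(i) for i in range(n)
        )
        if len(self.ids) != n:
            raise ValueError("ids length does not match rows")
        self.labels = None if labels is None else np.asarray(labels, dtype=float)
        if self.labels is not None and self.labels.shape != (n,):
            raise ValueError("labels length does not match rows")
        self.feature_names = (
            tuple(feature_names)
            if feature_names is not None
            else tuple(f"f{j}" for j in range(m))
        )
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match columns")
        self.center = bool(center)
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        label_col: str | None = None,
        id_col: str | None = None,
        **kwargs,
    ) -> "SeverityModel":
        """Build a model from a tidy DataFrame of features (rows = cutouts)."""
        df = data.copy()
        ids = None
        labels = None
        if id_col is not None:
            ids = [str(v) for v in df[id_col]]
            df = df.drop(columns=[id_col])
        if label_col is not None:
            labels = df[label_col].to_numpy(dtype=float)
            df = df.drop(columns=[label_col])
        if ids is None:
            ids = [str(i) for i in df.index]
        return cls(
            df.to_numpy(dtype=float),
            ids=ids,
            labels=labels,
            feature_names=[str(c) for c in df.columns],
            **kwargs,
        )

    def fit(self) -> "SeverityResults":
        """Eigendecompose the feature scatter and calibrate the PC1 score."""
        n, m = self.nobs, self.n_features
        center = self.X.mean(axis=0) if self.center else np.zeros(m)
        scale = np.ones(m)
        if self.standardize:
            sd = self.X.std(axis=0)
            scale = np.where(sd > 0, sd, 1.0)
        W = (self.X - center) / scale
        scatter = (W.T @ W) / (n * m)
        vals, vecs = np.linalg.eigh(scatter)  # ascending
        eigenvalues = np.clip(vals[::-1], 0.0, None)
        eigenvectors = vecs[:, ::-1]  # columns sorted by descending eigenvalue
        total = eigenvalues.sum()
        if total <= 0:
            raise DegenerateFitError("training matrix has zero variance")

        raw = W @ eigenvectors[:, 0]
        sign = 1.0
        if self.labels is not None and np.std(self.labels) > 0:
            # orient PC1 to increase with the ordinal severity hints
            rank_corr = np.corrcoef(
                pd.Series(raw).rank(), pd.Series(self.labels).rank()
            )[0, 1]
            if rank_corr < 0:
                sign = -1.0
        else:
            j = int(np.argmax(np.abs(eigenvectors[:, 0])))
            if eigenvectors[j, 0] < 0:
                sign = -1.0
        eigenvectors = eigenvectors.copy()
        eigenvectors[:, 0] *= sign
        raw = raw * sign

        pc1_min, pc1_max = float(raw.min()), float(raw.max())
        if not pc1_max > pc1_min:
            raise DegenerateFitError("PC1 projections are constant; cannot normalize")
        return SeverityResults(
            model=self,
            eigenvectors=eigenvectors,
            eigenvalues=eigenvalues,
            center=center,
            scale=scale,
            sign=sign,
            pc1_min=pc1_min,
            pc1_max=pc1_max,
            raw_pc1=raw,
        )


class SeverityResults:
    """Fitted severity model: eigenstructure, score calibration, reports."""

    def __init__(
        self,
        model: SeverityModel,
        eigenvectors: np.ndarray,
        eigenvalues: np.ndarray,
        center: np.ndarray,
        scale: np.ndarray,
        sign: float,
        pc1_min: float,
        pc1_max: float,
        raw_pc1: np.ndarray,
    ):
        self.model = model
        self.eigenvectors = eigenvectors
        self.eigenvalues = eigenvalues
        self.center = center
        self.scale = scale
        self.sign = sign
        self.pc1_min = pc1_min
        self.pc1_max = pc1_max
        self.raw_pc1 = raw_pc1
        self.feature_names = model.feature_names

    # -- eigenstructure ------------------------------------------------

    @property
    def variance_fractions(self) -> np.ndarray:
        """Eigenvalues normalized to sum to one."""
        return self.eigenvalues / self.eigenvalues.sum()

    def variance_fraction(self, k: int) -> float:
        """Fraction of total variation carried by component ``k`` (1-based)."""
        if not 1 <= k <= self.eigenvalues.size:
            raise IndexError(f"component index {k} out of range")
        return float(self.variance_fractions[k - 1])

    def scree(self, n_components: int = 10) -> pd.DataFrame:
        """Per-component eigenvalue and variance-fraction table."""
        k = min(n_components, self.eigenvalues.size)
        return pd.DataFrame(
            {
                "component": np.arange(1, k + 1),
                "eigenvalue": self.eigenvalues[:k],
                "variance_fraction": self.variance_fractions[:k],
            }
        )

    # -- scoring -------------------------------------------------------

    def _project(self, values: np.ndarray) -> float:
        w = (values - self.center) / self.scale
        return float(w @ self.eigenvectors[:, 0])

    def score(self, features, cutout_id: str = "") -> SeverityScore:
        """Project one feature vector onto PC1 and normalize to [0, 1].

        Projections outside the training range are clipped and flagged.
        """
        if isinstance(features, FeatureVector):
            cutout_id = cutout_id or features.cutout_id
            features = features.values
        values = np.asarray(features, dtype=float)
        if values.shape != (self.model.n_features,):
            raise ValueError(
                f"feature vector length {values.shape} != model {self.model.n_features}"
            )
        raw = self._project(values)
        unit = (raw - self.pc1_min) / (self.pc1_max - self.pc1_min)
        clipped = unit < 0.0 or unit > 1.0
        return SeverityScore(
            cutout_id=cutout_id,
            raw_pc1=raw,
            score=float(np.clip(unit, 0.0, 1.0)),
            clipped=bool(clipped),
        )

    def score_many(self, features, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Score a matrix/DataFrame of feature rows; returns a tidy table."""
        if isinstance(features, pd.DataFrame):
            if ids is None:
                ids = [str(i) for i in features.index]
            features = features.to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if ids is None:
            ids = [str(i) for i in range(arr.shape[0])]
        rows = [self.score(arr[i], cutout_id=str(ids[i])) for i in range(arr.shape[0])]
        return pd.DataFrame(
            {
                "cutout_id": [r.cutout_id for r in rows],
                "raw_pc1": [r.raw_pc1 for r in rows],
                "score": [r.score for r in rows],
                "clipped": [r.clipped for r in rows],
            }
        )

    @property
    def training_scores(self) -> pd.DataFrame:
        """Normalized scores of the training rows (min 0, max 1 attained)."""
        unit = (self.raw_pc1 - self.pc1_min) / (self.pc1_max - self.pc1_min)
        return pd.DataFrame(
            {"cutout_id": self.model.ids, "raw_pc1": self.raw_pc1, "score": unit}
        )

    # -- interpretation ------------------------------------------------

    def contributions(self) -> pd.Series:
        """First-eigenvector loading of every feature (unit L2 norm)."""
        return pd.Series(self.eigenvectors[:, 0], index=list(self.feature_names), name="pc1_loading")

    def contribution_groups(self) -> dict[str, pd.Series]:
        """Aggregate |loading| by generalizer statistic and by filter triple."""
        c = self.contributions().abs()
        by_stat = c.groupby([n.rsplit("_", 1)[-1] for n in c.index]).sum()
        by_triple = c.groupby([n.rsplit("_", 1)[0] for n in c.index]).sum()
        return {"by_stat": by_stat, "by_triple": by_triple.sort_values(ascending=False)}

    def summary(self) -> str:
        """Human-readable fit report."""
        frac = self.variance_fractions
        top = self.contributions().abs().sort_values(ascending=False).head(5)
        lines = [
            "PC1 severity score — PCA of Gabor texture features",
            "=" * 54,
            f"cutouts (n):            {self.model.nobs}",
            f"features (m):           {self.model.n_features}",
            f"centering:              {self.model.center}",
            f"standardized:           {self.model.standardize}",
            f"PC1 variance fraction:  {frac[0]:.4f}",
            f"PC2 variance fraction:  {frac[1]:.4f}" if frac.size > 1 else "",
            f"raw PC1 range:          [{self.pc1_min:.6g}, {self.pc1_max:.6g}]",
            f"orientation sign:       {self.sign:+.0f}",
            "",
            "largest |PC1 loading| features:",
        ]
        lines += [f"  {name:<28s} {self.contributions()[name]:+.4f}" for name in top.index]
        return "\n".join(line for line in lines if line != "")

    # -- persistence ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "layout_hash": _layout_hash(self.feature_names),
                "center_flag": self.model.center,
                "standardize_flag": self.model.standardize,
                "eigenvectors": self.eigenvectors.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
                "sign": self.sign,
                "pc1_min": self.pc1_min,
                "pc1_max": self.pc1_max,
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SeverityResults":
        d = json.loads(text)
        if _layout_hash(d["feature_names"]) != d["layout_hash"]:
            raise ValueError("model file layout hash mismatch")
        m = len(d["feature_names"])
        # reconstruct a minimal carrier model (no training rows retained)
        shell = SeverityModel.__new__(SeverityModel)
        shell.nobs, shell.n_features = 0, m
        shell.ids = ()
        shell.labels = None
        shell.feature_names = tuple(d["feature_names"])
        shell.center = bool(d["center_flag"])
        shell.standardize = bool(d["standardize_flag"])
        return cls(
            model=shell,
            eigenvectors=np.asarray(d["eigenvectors"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            sign=float(d["sign"]),
            pc1_min=float(d["pc1_min"]),
            pc1_max=float(d["pc1_max"]),
            raw_pc1=np.array([]),
        )

    @classmethod
    def load(cls, path) -> "SeverityResults":
        with open(path) as fh:
            return cls.from_json(fh.read())

    # -- plotting ------------------------------------------------------

    def plot_scree(self, n_components: int = 10, ax=None):
        """Bar chart of per-component variance fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.scree(n_components)
        ax.bar(tab["component"], 100 * tab["variance_fraction"])
        ax.set_xlabel("principal component")
        ax.set_ylabel("% of total variation")
        return ax

    def plot_contributions(self, ax=None):
        """PC1 loadings by feature, one marker style per generalizer."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        c = self.contributions()
        markers = {"mean": "D", "skew": "o", "entropy": "*"}
        for stat, marker in markers.items():
            mask = [n.endswith("_" + stat) for n in c.index]
            ax.plot(np.flatnonzero(mask), c[mask], marker, linestyle="none", label=stat)
        ax.axhline(0.0, color="0.7", lw=0.5)
        ax.set_xlabel("feature index (bank order)")
        ax.set_ylabel("PC1 loading")
        ax.legend()
        return ax
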