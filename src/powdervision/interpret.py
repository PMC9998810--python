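"""Model interpretation: input-sensitivity ranking and PCA.

Sensitivity of the trained classifier to each input descriptor is
measured by an error quotient: the validation RMS with that descriptor
suppressed (replaced by its training-set mean, i.e. zero after
standardisation) divided by the baseline validation RMS. A quotient
above 1 means the network deteriorates without the variable; the
descriptors are ranked by descending quotient. A pruning threshold
(default 1.05) only flags candidates — low-quotient variables are never
dropped automatically.

The top-ranked descriptors are then examined by principal component
analysis of their Pearson correlation matrix: eigenvalues sum to the
number of variables, each eigenvalue's share of that sum is its percent
of variance, and PC1/PC2 loadings are eigenvectors scaled by the square
root of their eigenvalue. A copy of a published 15-descriptor
correlation matrix ships as a fixture so the decomposition can be run
without any image data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .mlp import MLPModel, SplitIndex, rms_error

__all__ = [
    "SensitivityReport",
    "PCAResult",
    "sensitivity_analysis",
    "select_top_k",
    "correlation_matrix",
    "pca_eigen",
    "load_printed_correlation_matrix",
    "plot_pca",
]

DEFAULT_PRUNING_THRESHOLD = 1.05


@dataclass
class SensitivityReport:
    """Error quotients per input variable, sorted descending."""

    table: pd.DataFrame  # columns: rank, variable, quotient, prunable
    baseline_rms: float

    def quotient(self, variable: str) -> float:
        sel = self.table[self.table["variable"] == variable]
        if sel.empty:
            raise KeyError(variable)
        return float(sel["quotient"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sensitivity_analysis(
    model: MLPModel,
    table: pd.DataFrame,
    y: np.ndarray,
    split: SplitIndex,
    variables: list[str] | None = None,
    pruning_threshold: float = DEFAULT_PRUNING_THRESHOLD,
    method: str = "mean",
    seed: int = 0,
) -> SensitivityReport:
    """Rank input variables by validation-error quotient.

    ``method='mean'`` substitutes the training mean for the suppressed
    variable (missing-value substitution); ``method='permute'``
    shuffles the column instead, which preserves its marginal
    distribution. Ties in quotient are broken by canonical column
    order. A variable constant over all rows yields exactly 1.0 under
    mean substitution.
    """
    if variables is None:
        variables = list(model.feature_names)
    if hasattr(table, "columns"):
        x = table.loc[:, list(model.feature_names)].to_numpy(dtype=np.float64)
    else:
        x = np.asarray(table, dtype=np.float64)
    xva = x[split.validation]
    yva = y[split.validation]
    baseline = model.rms(xva, yva)
    if baseline == 0:
        raise ZeroDivisionError(
            "baseline validation RMS is zero; error quotients are undefined"
        )
    name_to_col = {name: i for i, name in enumerate(model.feature_names)}
    rng = np.random.default_rng(seed)
    rows = []
    for order, var in enumerate(variables):
        col = name_to_col[var]
        x_sup = xva.copy()
        if method == "mean":
            x_sup[:, col] = model.x_mean[col]
        elif method == "permute":
            x_sup[:, col] = x_sup[rng.permutation(len(x_sup)), col]
        else:
            raise ValueError(f"unknown suppression method {method!r}")
        quotient = rms_error(yva, model.forward(x_sup)) / baseline
        rows.append({"variable": var, "quotient": quotient, "_order": order})
    report = pd.DataFrame(rows)
    report = report.sort_values(
        ["quotient", "_order"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    report["prunable"] = report["quotient"] < pruning_threshold
    report = report[["rank", "variable", "quotient", "prunable"]]
    return SensitivityReport(table=report, baseline_rms=baseline)


def select_top_k(report: SensitivityReport, k: int = 15) -> list[str]:
    """The k variables with the largest error quotients, in rank order."""
    n = len(report.table)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ranked variables")
    return report.table.nsmallest(k, "rank")["variable"].tolist()


def correlation_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix of the chosen columns, unit diagonal."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    x = table.loc[:, variables].to_numpy(dtype=np.float64)
    sd = x.std(axis=0)
    dead = [v for v, s in zip(variables, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=variables, columns=variables)


@dataclass
class PCAResult:
    """Eigen-decomposition of a correlation matrix."""

    variables: list[str]
    eigenvalues: np.ndarray          # descending, tiny negatives clipped to 0
    percent_variance: np.ndarray     # 100 * lambda / p
    cumulative_percent: np.ndarray
    loadings: pd.DataFrame           # variables x (PC1, PC2)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
                "cumulative_percent": self.cumulative_percent,
            },
            index=[f"PC{i + 1}" for i in range(len(self.eigenvalues))],
        )


def pca_eigen(corr: pd.DataFrame | np.ndarray, atol: float = 1e-8) -> PCAResult:
    """PCA of a correlation matrix via symmetric eigen-decomposition.

    Eigenvalues are sorted descending; small negatives (possible when
    the matrix comes from rounded printed entries) are clipped at 0.
    Percent variance uses the variable count p as the total, which
    equals the exact eigenvalue sum of a true correlation matrix.
    Loading signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    if hasattr(corr, "columns"):
        names = list(corr.columns)
        mat = corr.to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(corr, dtype=np.float64)
        names = [f"var{i + 1}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=max(atol, 1e-8)):
        raise ValueError("matrix is asymmetric beyond tolerance")
    p = mat.shape[0]
    eigval, eigvec = np.linalg.eigh((mat + mat.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    percent = 100.0 * eigval / p
    loadings = eigvec[:, :2] * np.sqrt(eigval[:2])
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAResult(
        variables=names,
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        loadings=pd.DataFrame(loadings, index=names, columns=["PC1", "PC2"]),
    )


def load_printed_correlation_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """Load a lower-triangular correlation CSV and complete it by symmetry.

    Without a path, the packaged 15-descriptor reference matrix is
    used. Each CSV row is ``name,r1,...,rk`` with k entries up to and
    including the diagonal. Diagonal entries must equal 1 and every
    entry must lie in [-1, 1].
    """
    if path is None:
        ref = resources.files("powdervision.data") / "published_correlation_15.csv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    names, rows = [], []
    for rec in csv.reader(text.strip().splitlines()):
        if not rec or rec[0].startswith("#"):
            continue
        names.append(rec[0])
        rows.append([float(v) for v in rec[1:]])
    p = len(names)
    mat = np.zeros((p, p))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValueError(
                f"row {names[i]!r} has {len(row)} entries, expected {i + 1}"
            )
        if row[-1] != 1.0:
            raise ValueError(f"diagonal entry for {names[i]!r} is {row[-1]}, not 1")
        for j, v in enumerate(row):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"correlation ({names[i]}, {names[j]}) = {v} outside [-1, 1]")
            mat[i, j] = v
            mat[j, i] = v
    return pd.DataFrame(mat, index=names, columns=names)


def plot_pca(result: PCAResult, path: str | Path) -> None:
    """Two-panel figure: scree plot and PC1/PC2 loading vectors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.5))
    comps = np.arange(1, len(result.eigenvalues) + 1)
    ax1.bar(comps, result.percent_variance, color="#4878a8")
    ax1.plot(comps, result.cumulative_percent, "o-", color="#c44e52", ms=4)
    ax1.set_xlabel("principal component")
    ax1.set_ylabel("% of variance")
    ax1.set_title("Scree")

    for name, (u, v) in result.loadings.iterrows():
        ax2.annotate(
            "", xy=(u, v), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="#555555", lw=0.8),
        )
        ax2.text(u, v, name, fontsize=7)
    lim = float(np.abs(result.loadings.to_numpy()).max()) * 1.15 + 1e-9
    ax2.set_xlim(-lim, lim)
    ax2.set_ylim(-lim, lim)
    ax2.axhline(0, color="0.8", lw=0.5)
    ax2.axvline(0, color="0.8", lw=0.5)
    ax2.set_xlabel(f"PC1 ({result.percent_variance[0]:.2f}%)")
    ax2.set_ylabel(f"PC2 ({result.percent_variance[1]:.2f}%)")
    ax2.set_title("Variable loadings")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
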