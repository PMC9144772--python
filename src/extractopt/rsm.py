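"""Second-order response-surface fitting and ANOVA with lack-of-fit partition.

The full quadratic model in coded units has 1 + 2k + k(k-1)/2 terms:
intercept, linear, two-factor interactions and pure quadratics. Term sums
of squares are partial (drop-one-term) sums of squares, which for the
orthogonal linear block of a Box-Behnken design coincide with the
sequential ones.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentTable

__all__ = [
    "QuadraticModel",
    "AnovaRow",
    "AnovaTable",
    "design_matrix",
    "term_names",
    "fit_quadratic",
    "predict_quadratic",
    "anova_quadratic",
    "significance_marks",
    "anova_to_frame",
    "anova_to_text",
    "surface_grid",
]


def term_names(factor_names: Sequence[str]) -> list[str]:
    """Column labels of the quadratic design matrix, in canonical order."""
    k = len(factor_names)
    names = ["intercept"] + list(factor_names)
    names += [f"{factor_names[i]}*{factor_names[j]}" for i, j in combinations(range(k), 2)]
    names += [f"{n}^2" for n in factor_names]
    return names


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic design matrix [1, x_i, x_i x_j (i<j), x_i^2]."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Coefficients of a full second-order polynomial in coded units."""

    intercept: float
    linear: np.ndarray
    interaction: np.ndarray  # (k, k), upper triangle holds beta_ij (i < j)
    quadratic: np.ndarray
    factor_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        k = self.linear.size
        if self.interaction.shape != (k, k) or self.quadratic.shape != (k,):
            raise ValueError("coefficient dimensions are inconsistent")

    @property
    def n_factors(self) -> int:
        return self.linear.size

    @property
    def n_terms(self) -> int:
        k = self.n_factors
        return 1 + 2 * k + k * (k - 1) // 2

    def coef_vector(self) -> np.ndarray:
        """Coefficients in design-matrix column order."""
        k = self.n_factors
        inter = [self.interaction[i, j] for i, j in combinations(range(k), 2)]
        return np.concatenate(([self.intercept], self.linear, inter, self.quadratic))

    @classmethod
    def from_coef_vector(
        cls, beta: np.ndarray, k: int, factor_names: Sequence[str] | None = None
    ) -> "QuadraticModel":
        beta = np.asarray(beta, dtype=float)
        expected = 1 + 2 * k + k * (k - 1) // 2
        if beta.size != expected:
            raise ValueError(f"expected {expected} coefficients for k={k}, got {beta.size}")
        interaction = np.zeros((k, k))
        for idx, (i, j) in enumerate(combinations(range(k), 2)):
            interaction[i, j] = beta[1 + k + idx]
        return cls(
            intercept=float(beta[0]),
            linear=beta[1 : 1 + k].copy(),
            interaction=interaction,
            quadratic=beta[1 + k + k * (k - 1) // 2 :].copy(),
            factor_names=list(factor_names) if factor_names is not None else None,
        )

    def predict(self, coded: Sequence[float] | np.ndarray) -> float | np.ndarray:
        """Exact polynomial evaluation at coded point(s)."""
        coded = np.asarray(coded, dtype=float)
        single = coded.ndim == 1
        if coded.shape[-1] != self.n_factors:
            raise ValueError(
                f"point dimension {coded.shape[-1]} != model dimension {self.n_factors}"
            )
        y = design_matrix(coded) @ self.coef_vector()
        return float(y[0]) if single else y

    def quadratic_form(self) -> tuple[np.ndarray, np.ndarray]:
        """(B, b) with predict(x) = intercept + b.x + x.B.x, B symmetric."""
        k = self.n_factors
        B = np.diag(self.quadratic).astype(float)
        for i, j in combinations(range(k), 2):
            B[i, j] += self.interaction[i, j] / 2.0
            B[j, i] += self.interaction[i, j] / 2.0
        return B, self.linear.copy()


def fit_quadratic(table: ExperimentTable, response: str = "composite") -> QuadraticModel:
    """Ordinary least squares fit of the full quadratic on coded levels."""
    y = table.response(response)
    D = design_matrix(table.coded)
    n, p = D.shape
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} terms, have {n}")
    rank = np.linalg.matrix_rank(D)
    if rank < p:
        names = term_names([f.name for f in table.factors])
        _, R = np.linalg.qr(D)
        aliased = [names[i] for i in range(p) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return QuadraticModel.from_coef_vector(
        beta, len(table.factors), [f.name for f in table.factors]
    )


def predict_quadratic(model: QuadraticModel, coded: Sequence[float]) -> float | np.ndarray:
    return model.predict(coded)


def significance_marks(p: float) -> str:
    """Star notation at the 0.05 / 0.01 / 0.001 thresholds."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AnovaRow:
    term: str
    ss: float
    df: int
    ms: float
    f: float | None
    p: float | None
    mark: str = ""


@dataclass
class AnovaTable:
    """Term-wise ANOVA with lack-of-fit partition and fit statistics."""

    model_row: AnovaRow
    term_rows: list[AnovaRow]
    residual: AnovaRow
    lack_of_fit: AnovaRow | None
    pure_error: AnovaRow | None
    total_ss: float
    total_df: int
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    warnings: list[str] = field(default_factory=list)

    def row(self, term: str) -> AnovaRow:
        for r in self.term_rows:
            if r.term == term:
                return r
        raise KeyError(f"no ANOVA row for term {term!r}")


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Within-replicate-group SS and df (groups keyed by exact coded levels)."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(coded):
        groups.setdefault(tuple(row.tolist()), []).append(i)
    ss = 0.0
    df = 0
    for idx in groups.values():
        if len(idx) > 1:
            v = y[idx]
            ss += float(((v - v.mean()) ** 2).sum())
            df += len(idx) - 1
    return ss, df


def anova_quadratic(
    model: QuadraticModel, table: ExperimentTable, response: str = "composite"
) -> AnovaTable:
    """Full ANOVA of a fitted quadratic: partial SS per term, lack of fit,
    R-squared family and PRESS-based predicted R-squared."""
    y = table.response(response)
    D = design_matrix(table.coded)
    n, p = D.shape
    beta = model.coef_vector()
    resid = y - D @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    df_model, df_res = p - 1, n - p
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res

    warns: list[str] = []
    names = term_names(
        model.factor_names
        if model.factor_names is not None
        else [f"x{i + 1}" for i in range(model.n_factors)]
    )

    # partial (drop-one-term) SS
    term_rows: list[AnovaRow] = []
    for col in range(1, p):
        keep = [c for c in range(p) if c != col]
        beta_r, *_ = np.linalg.lstsq(D[:, keep], y, rcond=None)
        resid_r = y - D[:, keep] @ beta_r
        ss_term = float(resid_r @ resid_r) - ss_res
        f_term = ss_term / ms_res if ms_res > 0 else np.inf
        p_term = float(stats.f.sf(f_term, 1, df_res))
        term_rows.append(
            AnovaRow(names[col], ss_term, 1, ss_term, f_term, p_term,
                     significance_marks(p_term))
        )

    f_model = (ss_model / df_model) / ms_res if ms_res > 0 else np.inf
    p_model = float(stats.f.sf(f_model, df_model, df_res))
    model_row = AnovaRow("model", ss_model, df_model, ss_model / df_model,
                         f_model, p_model, significance_marks(p_model))
    residual_row = AnovaRow("residual", ss_res, df_res, ms_res, None, None)

    # lack-of-fit / pure-error split
    ss_pe, df_pe = _pure_error(table.coded, y)
    lof_row = pe_row = None
    if df_pe == 0:
        warns.append("no replicated points: lack-of-fit row unavailable")
    else:
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        pe_row = AnovaRow("pure error", ss_pe, df_pe, ss_pe / df_pe, None, None)
        if df_lof <= 0:
            warns.append("no lack-of-fit degrees of freedom")
        elif ss_pe <= 0:
            warns.append("degenerate pure error (all replicates identical); "
                         "lack-of-fit F infinite")
            lof_row = AnovaRow("lack of fit", ss_lof, df_lof, ss_lof / df_lof,
                               np.inf, 0.0, significance_marks(0.0))
        else:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            lof_row = AnovaRow("lack of fit", ss_lof, df_lof, ss_lof / df_lof,
                               f_lof, p_lof, significance_marks(p_lof))

    # leverage-based PRESS
    h = np.einsum("ij,ji->i", D, np.linalg.solve(D.T @ D, D.T))
    press = float(((resid / (1.0 - h)) ** 2).sum())

    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1))
    pred_r2 = 1.0 - press / ss_tot

    # additivity invariants of the decomposition
    assert abs((ss_model + ss_res) - ss_tot) <= 1e-6 * max(ss_tot, 1.0)
    assert df_model + df_res == n - 1
    if pe_row is not None and lof_row is not None:
        assert abs((lof_row.ss + pe_row.ss) - ss_res) <= 1e-6 * max(ss_res, 1.0)

    return AnovaTable(
        model_row=model_row,
        term_rows=term_rows,
        residual=residual_row,
        lack_of_fit=lof_row,
        pure_error=pe_row,
        total_ss=ss_tot,
        total_df=n - 1,
        r2=r2,
        adj_r2=adj_r2,
        pred_r2=pred_r2,
        press=press,
        warnings=warns,
    )


def anova_to_frame(anova: AnovaTable) -> pd.DataFrame:
    rows = [anova.model_row] + anova.term_rows + [anova.residual]
    if anova.lack_of_fit is not None:
        rows.append(anova.lack_of_fit)
    if anova.pure_error is not None:
        rows.append(anova.pure_error)
    return pd.DataFrame(
        [
            {
                "source": r.term,
                "sum_of_squares": r.ss,
                "df": r.df,
                "mean_square": r.ms,
                "F": r.f,
                "p": r.p,
                "significance": r.mark,
            }
            for r in rows
        ]
    )


def anova_to_text(anova: AnovaTable) -> str:
    """Aligned plain-text ANOVA report."""
    df = anova_to_frame(anova)
    lines = [
        f"{'Source':<28}{'SS':>12}{'df':>5}{'MS':>12}{'F':>12}{'p':>10}  Sig"
    ]
    for _, r in df.iterrows():
        f_str = "" if pd.isna(r["F"]) else f"{r['F']:.4f}"
        p_str = "" if pd.isna(r["p"]) else ("<0.0001" if r["p"] < 1e-4 else f"{r['p']:.4f}")
        lines.append(
            f"{r['source']:<28}{r['sum_of_squares']:>12.4f}{int(r['df']):>5}"
            f"{r['mean_square']:>12.4f}{f_str:>12}{p_str:>10}  {r['significance']}"
        )
    lines.append(f"{'Total':<28}{anova.total_ss:>12.4f}{anova.total_df:>5}")
    lines.append(f"R^2           {anova.r2:.4f}")
    lines.append(f"Adjusted R^2  {anova.adj_r2:.4f}")
    lines.append(f"Predicted R^2 {anova.pred_r2:.4f}")
    return "\n".join(lines)


def surface_grid(
    model: QuadraticModel,
    factor_i: int,
    factor_j: int,
    step: float = 0.05,
) -> pd.DataFrame:
    """Predicted response on a coded grid over one factor pair (others at 0)."""
    if not 0 < step <= 1:
        raise ValueError("step must be in (0, 1]")
    axis = np.arange(-1.0, 1.0 + step / 2, step)
    xi, xj = np.meshgrid(axis, axis, indexing="ij")
    pts = np.zeros((xi.size, model.n_factors))
    pts[:, factor_i] = xi.ravel()
    pts[:, factor_j] = xj.ravel()
    return pd.DataFrame(
        {"xi": xi.ravel(), "xj": xj.ravel(), "predicted": model.predict(pts)}
    )
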