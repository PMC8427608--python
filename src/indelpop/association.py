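"""Fixed-effect least-squares association of indel genotype with traits.

The analysis fits, per trait, one of two fixed-effect linear models to an F2
resource population:

  Model I :  y = mu + genotype + sex + hatch + family + e
  Model II:  y = mu + genotype + sex + hatch + family + b*(W - Wbar) + e

where W is individual slaughter weight centered at the analyzed subset's
mean.  Factors enter under sum-to-zero constraints, so the intercept is the
grand (equal-weight) mean and the least-squares mean of genotype g is
``mu + G_g`` with every other factor balanced and the covariate at its mean.

Genotype significance is a partial (Type-III style) F-test comparing the
full fit against the fit without the genotype columns — appropriate for the
unbalanced genotype classes of an intercross.  Pairwise genotype contrasts
use Bonferroni-adjusted t-tests and are summarised as a compact letter
display.  Additive and dominance effects follow the Falconer convention:

  a = (mean_II - mean_DD) / 2
  d = mean_ID - (mean_II + mean_DD)/2

i.e. the genotypic values are +a, d, -a for II, ID, DD.  The classical
regression codings (additive II/ID/DD = +1/0/-1; dominance contrast
-1/+1/-1) estimate the same quantities up to scale — the +-1 dominance
contrast's coefficient equals d/2 — so effects are reported on the
genotypic-value scale throughout.

The public surface follows the model/results idiom: build a
:class:`GenotypeTraitModel` from data, call :meth:`~GenotypeTraitModel.fit`,
inspect the returned :class:`GenotypeTraitResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import ValidationError
from .traits import model_for_trait

__all__ = [
    "GENOTYPE_ORDER", "ADDITIVE_CODE", "DOMINANCE_CODE",
    "DesignInfo", "build_design", "fit_ls", "LsFit",
    "GenotypeTraitModel", "GenotypeTraitResults",
    "AssocResult", "trait_scan", "compact_letter_display",
]

GENOTYPE_ORDER = ("DD", "ID", "II")
#: Additive genotype coding (number of insertion alleles, centered).
ADDITIVE_CODE = {"II": 1.0, "ID": 0.0, "DD": -1.0}
#: Dominance *contrast* coding; its regression coefficient equals d/2.
DOMINANCE_CODE = {"II": -1.0, "ID": 1.0, "DD": -1.0}

_FACTORS = ("genotype", "sex", "hatch", "family")


def _sum_coding(values: pd.Series, levels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding: k-1 columns, last level coded -1."""
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(arr == lev, 1.0, np.where(arr == levels[-1], -1.0, 0.0))
    names = [f"{values.name}[{lev}]" for lev in levels[:-1]]
    return cols, names


def _level_codes(level: str, levels: list[str]) -> np.ndarray:
    """Row of the sum-coding for one level (used to build LS-mean contrasts)."""
    k = len(levels)
    if level == levels[-1]:
        return -np.ones(k - 1)
    row = np.zeros(k - 1)
    row[levels.index(level)] = 1.0
    return row


@dataclass
class DesignInfo:
    """A fully built design matrix plus the bookkeeping needed downstream."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    genotype_levels: list[str]
    genotype_cols: list[int]
    lsmean_contrasts: dict[str, np.ndarray]
    class_n: dict[str, int]
    model: str
    trait: str
    index: pd.Index  # rows of the source frame that entered the fit


def build_design(data: pd.DataFrame, trait: str, model: str = "I") -> DesignInfo:
    """Build the full-rank sum-to-zero design for one trait.

    ``data`` must carry genotype, sex, hatch, family, the trait column and —
    for Model II — slaughter_weight.  Rows with a missing trait value (or
    missing covariate under Model II) are dropped listwise here.

    Factors observed at a single level are dropped with a warning; a factor
    observed with an empty level simply degrades to fewer columns.  A
    rank-deficient design raises naming the confounded factors.
    """
    if model not in ("I", "II"):
        raise ValueError(f"model must be 'I' or 'II', got {model!r}")
    if trait not in data.columns:
        raise ValidationError(f"trait column {trait!r} not in data")
    needed = list(_FACTORS) + [trait] + (["slaughter_weight"] if model == "II" else [])
    sub = data.dropna(subset=needed)
    if sub.empty:
        raise ValidationError(f"no complete rows for trait {trait!r}")

    n = len(sub)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    factor_levels: dict[str, list[str]] = {}
    block_cols: dict[str, list[int]] = {}
    for factor in _FACTORS:
        col = sub[factor].astype(str)
        col.name = factor
        levels = sorted(col.unique())
        factor_levels[factor] = levels
        if len(levels) < 2:
            if factor == "genotype":
                raise ValidationError("only one genotype class present; nothing to test")
            warnings.warn(f"factor {factor!r} has a single level and was dropped")
            block_cols[factor] = []
            continue
        mat, colnames = _sum_coding(col, levels)
        start = sum(b.shape[1] for b in blocks)
        block_cols[factor] = list(range(start, start + mat.shape[1]))
        blocks.append(mat)
        names.extend(colnames)

    if model == "II":
        w = sub["slaughter_weight"].to_numpy(dtype=float)
        blocks.append((w - w.mean()).reshape(-1, 1))
        names.append("slaughter_weight_centered")

    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        confounded = [
            f for f in _FACTORS
            if block_cols[f]
            and np.linalg.matrix_rank(np.delete(X, block_cols[f], axis=1)) == rank
        ]
        raise ValidationError(
            f"rank-deficient design for trait {trait!r}: "
            f"confounded factor(s) {confounded or 'unknown'}"
        )

    geno_levels = factor_levels["genotype"]
    contrasts = {}
    for g in geno_levels:
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        codes = _level_codes(g, geno_levels)
        for j, idx in enumerate(block_cols["genotype"]):
            c[idx] = codes[j]
        contrasts[g] = c

    class_n = sub["genotype"].astype(str).value_counts().to_dict()
    return DesignInfo(
        X=X,
        y=sub[trait].to_numpy(dtype=float),
        columns=names,
        genotype_levels=geno_levels,
        genotype_cols=block_cols["genotype"],
        lsmean_contrasts=contrasts,
        class_n={g: int(class_n[g]) for g in geno_levels},
        model=model,
        trait=trait,
        index=sub.index,
    )


@dataclass
class LsFit:
    """Ordinary least-squares fit: coefficients and their covariance."""

    params: np.ndarray
    cov_params: np.ndarray
    ssr: float
    df_resid: int
    resid: np.ndarray
    sigma2: float


def fit_ls(X: np.ndarray, y: np.ndarray) -> LsFit:
    """Fit y = X b + e by ordinary least squares.

    Requires more observations than columns; a singular design raises.
    """
    n, p = X.shape
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} rows to fit {p} columns, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("singular design matrix")
    res = sm.OLS(y, X).fit()
    return LsFit(
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        ssr=float(res.ssr),
        df_resid=int(res.df_resid),
        resid=np.asarray(res.resid),
        sigma2=float(res.ssr / res.df_resid),
    )


def _contrast(fit: LsFit, c: np.ndarray) -> tuple[float, float]:
    """Estimate and standard error of a linear contrast c'b."""
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params @ c))
    return est, se


def compact_letter_display(
    means: dict[str, float], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Classes share a letter iff their pairwise difference is *not* in
    ``significant``.  Letters are assigned starting from the class with the
    largest mean, so 'a' always marks the top group.  The result is invariant
    to the input ordering of ``means``.
    """
    groups = sorted(means, key=means.get, reverse=True)
    columns: list[set[str]] = [set(groups)]
    for pair in significant:
        i, j = tuple(pair)
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for cand in (col - {i}, col - {j}):
                if cand and not any(cand <= other for other in columns):
                    columns.append(cand)
    # order columns by their best-ranked member so 'a' goes to the top mean
    columns.sort(key=lambda col: min(groups.index(g) for g in col))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


@dataclass(frozen=True)
class GenotypeCell:
    """One genotype's entry in an association table row."""

    n: int
    ls_mean: float
    sem: float
    letters: str


@dataclass(frozen=True)
class AssocResult:
    """One trait's association summary (the row type of a results table)."""

    trait_code: str
    model: str
    cells: dict[str, GenotypeCell]
    p_overall: float
    additive_a: float | None
    additive_se: float | None
    dominance_d: float | None
    dominance_se: float | None


class GenotypeTraitModel:
    """Fixed-effect least-squares model of one trait on indel genotype.

    Parameters
    ----------
    data : DataFrame
        Merged phenotype + genotype table with columns ``genotype``, ``sex``,
        ``hatch``, ``family``, ``slaughter_weight`` and the trait.
    trait : str
        Trait column to analyse.
    model : {"I", "II", "auto"}
        "I" = factors only; "II" = add centered slaughter weight as a
        covariate; "auto" chooses by trait category (body-size traits get
        the covariate).
    alpha : float
        Familywise significance level for the pairwise letter display
        (each of the 3 contrasts is tested at ``alpha / 3``).

    Examples
    --------
    >>> model = GenotypeTraitModel.from_tables(phenos, genos, trait="BW2")
    >>> res = model.fit()
    >>> res.p_overall, res.additive_a
    """

    def __init__(self, data: pd.DataFrame, trait: str, model: str = "I",
                 alpha: float = 0.05) -> None:
        if model == "auto":
            model = model_for_trait(trait)
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.data = data
        self.trait = trait
        self.model = model
        self.alpha = alpha
        self.design = build_design(data, trait, model)

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                    trait: str, model: str = "auto", alpha: float = 0.05
                    ) -> "GenotypeTraitModel":
        """Merge a phenotype table with genotype calls on ``individual_id``."""
        geno = genotypes[["individual_id", "genotype"]].dropna(subset=["genotype"])
        merged = phenotypes.merge(geno, on="individual_id", how="inner")
        return cls(merged, trait=trait, model=model, alpha=alpha)

    def fit(self) -> "GenotypeTraitResults":
        d = self.design
        full = fit_ls(d.X, d.y)
        # partial F-test: refit without the genotype columns on the same rows
        X_red = np.delete(d.X, d.genotype_cols, axis=1)
        reduced = fit_ls(X_red, d.y)
        q = len(d.genotype_cols)
        if full.sigma2 == 0.0:
            # perfectly fitted response: the F-test degenerates
            f_stat = np.inf if reduced.ssr > full.ssr else 0.0
            p_overall = 0.0 if reduced.ssr > full.ssr else 1.0
        else:
            f_stat = ((reduced.ssr - full.ssr) / q) / full.sigma2
            p_overall = float(stats.f.sf(f_stat, q, full.df_resid))
        return GenotypeTraitResults(self, full, f_stat=float(f_stat),
                                    p_overall=p_overall)


class GenotypeTraitResults:
    """Results of a :class:`GenotypeTraitModel` fit.

    Attributes
    ----------
    ls_means : DataFrame
        Per-genotype n, least-squares mean, SEM and letter group.
    pairwise : DataFrame
        The genotype contrasts with estimates, SEs and p-values; the
        Bonferroni-adjusted threshold used is ``alpha / n_contrasts``.
    p_overall : float
        Partial F-test p-value for the genotype factor.
    additive_a, dominance_d : float
        Falconer additive and dominance effects with standard errors
        (``additive_se``, ``dominance_se``); None when a homozygote class
        is absent.
    """

    def __init__(self, model: GenotypeTraitModel, fit: LsFit,
                 f_stat: float, p_overall: float) -> None:
        self.model = model
        self.fit = fit
        self.f_stat = f_stat
        self.p_overall = p_overall
        self.nobs = len(model.design.y)
        self.df_resid = fit.df_resid
        d = model.design

        means, sems = {}, {}
        for g in d.genotype_levels:
            means[g], sems[g] = _contrast(fit, d.lsmean_contrasts[g])
        self._means, self._sems = means, sems

        pairs = list(combinations(d.genotype_levels, 2))
        self.n_contrasts = len(pairs)
        self.alpha_adjusted = model.alpha / max(self.n_contrasts, 1)
        rows, significant = [], set()
        for g1, g2 in pairs:
            c = d.lsmean_contrasts[g1] - d.lsmean_contrasts[g2]
            est, se = _contrast(fit, c)
            if se == 0.0:  # zero residual variance
                t = np.inf if est != 0.0 else 0.0
                p = 0.0 if est != 0.0 else 1.0
            else:
                t = est / se
                p = float(2 * stats.t.sf(abs(t), fit.df_resid))
            if p < self.alpha_adjusted:
                significant.add(frozenset((g1, g2)))
            rows.append((g1, g2, est, se, t, p, p < self.alpha_adjusted))
        self.pairwise = pd.DataFrame(
            rows, columns=["g1", "g2", "estimate", "se", "t", "p", "significant"]
        )
        self._letters = compact_letter_display(means, significant)

        self.ls_means = pd.DataFrame(
            {
                "genotype": d.genotype_levels,
                "n": [d.class_n[g] for g in d.genotype_levels],
                "ls_mean": [means[g] for g in d.genotype_levels],
                "sem": [sems[g] for g in d.genotype_levels],
                "letters": [self._letters[g] for g in d.genotype_levels],
            }
        ).set_index("genotype")

        if {"II", "DD", "ID"} <= set(d.genotype_levels):
            c_a = (d.lsmean_contrasts["II"] - d.lsmean_contrasts["DD"]) / 2.0
            c_d = d.lsmean_contrasts["ID"] - (
                d.lsmean_contrasts["II"] + d.lsmean_contrasts["DD"]) / 2.0
            self.additive_a, self.additive_se = _contrast(fit, c_a)
            self.dominance_d, self.dominance_se = _contrast(fit, c_d)
        else:
            warnings.warn(
                "additive/dominance effects undefined: genotype class(es) "
                f"{sorted({'II', 'ID', 'DD'} - set(d.genotype_levels))} absent"
            )
            self.additive_a = self.additive_se = None
            self.dominance_d = self.dominance_se = None

    def to_assoc_result(self) -> AssocResult:
        d = self.model.design
        cells = {
            g: GenotypeCell(
                n=d.class_n[g],
                ls_mean=self._means[g],
                sem=self._sems[g],
                letters=self._letters[g],
            )
            for g in d.genotype_levels
        }
        return AssocResult(
            trait_code=self.model.trait,
            model=self.model.model,
            cells=cells,
            p_overall=self.p_overall,
            additive_a=self.additive_a,
            additive_se=self.additive_se,
            dominance_d=self.dominance_d,
            dominance_se=self.dominance_se,
        )

    def summary(self) -> str:
        """Human-readable per-trait summary table."""
        lines = [
            f"Trait {self.model.trait} — Model {self.model.model}, "
            f"n = {self.nobs}, residual df = {self.df_resid}",
            f"Genotype F = {self.f_stat:.3f}, P = {self.p_overall:.4g}",
            f"{'genotype':>8} {'n':>5} {'LS mean':>12} {'SEM':>10} {'letters':>8}",
        ]
        for g, row in self.ls_means.iterrows():
            lines.append(
                f"{g:>8} {int(row['n']):>5} {row['ls_mean']:>12.4f} "
                f"{row['sem']:>10.4f} {row['letters']:>8}"
            )
        if self.additive_a is not None:
            lines.append(
                f"additive a = {self.additive_a:.4f} ± {self.additive_se:.4f}, "
                f"dominance d = {self.dominance_d:.4f} ± {self.dominance_se:.4f}"
            )
        return "\n".join(lines)


def trait_scan(phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
               traits: list[str], model_policy: str = "auto",
               alpha: float = 0.05) -> list[AssocResult]:
    """Run the per-trait association across a trait list.

    Each trait is analysed at familywise ``alpha`` for its own letter display;
    no correction is applied across traits.  Traits absent from the phenotype
    table are skipped with a warning.
    """
    results: list[AssocResult] = []
    for trait in traits:
        if trait not in phenotypes.columns:
            warnings.warn(f"trait {trait!r} not in phenotype table; skipped")
            continue
        model = GenotypeTraitModel.from_tables(
            phenotypes, genotypes, trait=trait, model=model_policy, alpha=alpha
        )
        results.append(model.fit().to_assoc_result())
    return results
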