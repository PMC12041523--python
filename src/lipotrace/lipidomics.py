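"""Internal-standard lipid quantification, differential abundance, and VIP.

The module's contract starts at a samples x species intensity table (the
output of an upstream LC-MS identification pipeline).  Quantification is
single-point: each lipid class is spiked with one non-endogenous internal
standard at a known amount, and an analyte's amount is its intensity ratio to
the class standard times the spiked nmol::

    amount(s, j) = intensity(s, j) / intensity(IS_class(s), j) * nmol(IS_class(s))

Any per-sample global intensity gain cancels in the ratio.  Downstream:
per-sample normalization (per ug protein or total-pool fractions), class
profiles, Welch t-tests on log2 amounts with volcano significance tiers
(p < 0.05 / 0.01 / 0.001, |log2FC| >= 2), and PLS-DA variable importance in
projection (VIP) with the conventional VIP > 1 selection cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests


class StandardCoverageError(ValueError):
    """A lipid class in the table has no internal standard (even via aliases)."""


# --------------------------------------------------------------------------
# standards map
# --------------------------------------------------------------------------


@dataclass
class InternalStandardMap:
    """Class label -> (standard species name, spiked amount in nmol)."""

    table: pd.DataFrame  # index: class; columns: standard, nmol

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"more than one standard for class(es) {dup}")
        if np.any(self.table["nmol"] <= 0):
            raise ValueError("standard amounts must be positive")

    @property
    def classes(self) -> set[str]:
        return set(self.table.index)

    def standard_for(self, cls: str) -> tuple[str, float]:
        row = self.table.loc[cls]
        return str(row["standard"]), float(row["nmol"])

    @classmethod
    def from_csv(cls, path) -> "InternalStandardMap":
        df = pd.read_csv(path, comment="#").set_index("class")
        return cls(df)


def load_standards(path=None) -> InternalStandardMap:
    """Packaged class-matched standards (override with your own CSV path)."""
    if path is not None:
        return InternalStandardMap.from_csv(path)
    ref = resources.files("lipotrace.data").joinpath("internal_standards.csv")
    with resources.as_file(ref) as p:
        return InternalStandardMap.from_csv(p)


def load_class_aliases(path=None) -> dict[str, str]:
    """Editable subclass -> parent-class fallback map (e.g. PC[O] -> PC)."""
    if path is None:
        ref = resources.files("lipotrace.data").joinpath("class_aliases.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return dict(zip(df["alias"], df["parent"]))


# --------------------------------------------------------------------------
# table container
# --------------------------------------------------------------------------


@dataclass
class LipidTable:
    """Samples x species intensities with class annotations and metadata.

    ``intensities`` rows are samples, columns are species (including the
    internal-standard species); ``species_class`` maps every column to a
    class; ``groups`` maps samples to condition labels; ``protein_ug`` is the
    optional per-sample protein amount used for protein normalization.
    """

    intensities: pd.DataFrame
    species_class: pd.Series
    groups: pd.Series | None = None
    protein_ug: pd.Series | None = None

    def __post_init__(self) -> None:
        if np.any(self.intensities.to_numpy() < 0):
            raise ValueError("intensities must be non-negative")
        missing = set(self.intensities.columns) - set(self.species_class.index)
        if missing:
            raise ValueError(f"species without class annotation: {sorted(missing)}")

    @classmethod
    def from_csv(
        cls, intensities_csv, classes_csv, groups_csv=None, protein_csv=None
    ) -> "LipidTable":
        """Load from plain CSVs: intensities (samples x species, first column
        = sample id), classes (species,class), optional groups (sample,group)
        and protein (sample,protein_ug)."""
        inten = pd.read_csv(intensities_csv, index_col=0)
        classes = pd.read_csv(classes_csv).set_index("species")["class"]
        groups = (
            pd.read_csv(groups_csv).set_index("sample")["group"]
            if groups_csv
            else None
        )
        protein = (
            pd.read_csv(protein_csv).set_index("sample")["protein_ug"]
            if protein_csv
            else None
        )
        return cls(inten, classes, groups, protein)


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def _resolve_class(
    cls: str, standards: InternalStandardMap, aliases: dict[str, str]
) -> str:
    if cls in standards.classes:
        return cls
    if cls in aliases and aliases[cls] in standards.classes:
        return aliases[cls]
    raise StandardCoverageError(
        f"class {cls!r} has no internal standard and no alias to one"
    )


def normalize_to_is(
    table: LipidTable,
    standards: InternalStandardMap | None = None,
    aliases: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Convert intensities to amounts (nmol) via class-matched standards.

    Internal-standard columns are consumed (used as denominators, dropped
    from the output).  Missing standards raise
    :class:`StandardCoverageError`; a zero standard intensity raises with the
    offending sample named.
    """
    standards = standards or load_standards()
    aliases = aliases if aliases is not None else load_class_aliases()

    std_names = {standards.standard_for(c)[0]: c for c in standards.classes}
    analytes = [c for c in table.intensities.columns if c not in std_names]

    amounts = pd.DataFrame(index=table.intensities.index, dtype=float)
    for sp in analytes:
        cls = _resolve_class(str(table.species_class[sp]), standards, aliases)
        std_name, nmol = standards.standard_for(cls)
        if std_name not in table.intensities.columns:
            raise StandardCoverageError(
                f"standard {std_name!r} (class {cls!r}) not present in the table"
            )
        std_int = table.intensities[std_name]
        bad = std_int[std_int <= 0]
        if len(bad):
            raise ValueError(
                f"standard {std_name!r} has non-positive intensity in "
                f"sample(s) {bad.index.tolist()}"
            )
        amounts[sp] = table.intensities[sp] / std_int * nmol
    return amounts


def normalize_sample(
    amounts: pd.DataFrame,
    mode: str = "total_pool",
    protein_ug: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample normalization of the amounts table.

    ``mode='protein'`` divides by the sample's protein amount (nmol per ug);
    ``mode='total_pool'`` divides by the sample's summed amounts so each row
    becomes fractions of the total lipid pool (summing to 1).
    """
    if mode == "protein":
        if protein_ug is None:
            raise ValueError("protein_ug required for mode='protein'")
        protein = protein_ug.reindex(amounts.index)
        if protein.isna().any() or np.any(protein <= 0):
            raise ValueError("every sample needs a positive protein amount")
        return amounts.div(protein, axis=0)
    if mode == "total_pool":
        totals = amounts.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("a sample has zero total lipid amount")
        return amounts.div(totals, axis=0)
    raise ValueError("mode must be 'protein' or 'total_pool'")


def class_profiles(amounts: pd.DataFrame, species_class: pd.Series) -> pd.DataFrame:
    """Class x sample relative abundances (class sums / total lipid sum)."""
    classes = species_class.reindex(amounts.columns)
    sums = amounts.T.groupby(classes).sum()  # class x sample
    return sums.div(sums.sum(axis=0), axis=1)


# --------------------------------------------------------------------------
# differential abundance
# --------------------------------------------------------------------------

SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)
FC_FLAG_THRESHOLD = 2.0  # |log2FC| at the volcano's vertical guides


def differential(
    amounts: pd.DataFrame, groups: pd.Series, reference: str | None = None
) -> pd.DataFrame:
    """Per-species Welch t-test on log2 amounts plus volcano annotation.

    Returns a DataFrame indexed by species with ``log2fc`` (log2 ratio of
    group means, case over reference), ``p`` (two-sided Welch t on log2
    amounts), ``tier`` (strictest of 0.05/0.01/0.001 met, else NaN),
    ``large_fc`` (|log2FC| >= 2), ``significant`` (p <= 0.01, the volcano
    coloring rule), and a Benjamini-Hochberg ``fdr`` column as an extra.
    """
    groups = groups.reindex(amounts.index)
    labels = groups.dropna().unique().tolist()
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if reference is None:
        reference = labels[0]
    case = [g for g in labels if g != reference][0]
    a = amounts.loc[groups == case]
    b = amounts.loc[groups == reference]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")

    with np.errstate(divide="ignore"):
        log2_a = np.log2(a.to_numpy())
        log2_b = np.log2(b.to_numpy())
    t, p = stats.ttest_ind(log2_a, log2_b, equal_var=False)
    log2fc = np.log2(a.mean(axis=0) / b.mean(axis=0))

    tiers = np.full(len(p), np.nan)
    for thr in SIGNIFICANCE_TIERS:  # ascending strictness
        tiers = np.where(p < thr, thr, tiers)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "tier": tiers,
            "large_fc": np.abs(log2fc) >= FC_FLAG_THRESHOLD,
            "significant": p <= 0.01,
        },
        index=amounts.columns,
    )
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# PLS-DA VIP
# --------------------------------------------------------------------------


@dataclass
class VIPResult:
    """Variable importance in projection per species.

    The mean squared VIP equals 1 by construction (sum VIP^2 = number of
    retained species), so VIP > 1 marks above-average contributors.
    """

    vip: pd.Series
    n_components: int
    group_encoding: dict[str, float]
    dropped: list[str]


def vip_scores(
    amounts: pd.DataFrame,
    groups: pd.Series,
    ncomp: int = 2,
    log_transform: bool = False,
) -> VIPResult:
    """PLS-DA (NIPALS, autoscaled predictors) VIP scores.

    The group label is encoded 0/1 and centered; predictors are autoscaled
    (zero mean, unit variance).  With weight vectors ``w_a``, scores ``t_a``
    and response loadings ``q_a``, the variance of y explained by component
    ``a`` is ``SSY_a = q_a^2 * t_a.t_a`` and::

        VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a )

    Zero-variance species are dropped with a warning before autoscaling.
    """
    groups = groups.reindex(amounts.index)
    labels = sorted(groups.dropna().unique().tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    counts = groups.value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 samples")

    X = amounts.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X)
    keep = X.std(axis=0, ddof=1) > 0
    dropped = [c for c, k in zip(amounts.columns, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance species: {dropped}",
            stacklevel=2,
        )
    X = X[:, keep]
    cols = [c for c, k in zip(amounts.columns, keep) if k]
    if not cols:
        raise ValueError("no species with variance left to fit")

    encoding = {labels[0]: 0.0, labels[1]: 1.0}
    y = groups.map(encoding).to_numpy(dtype=float)

    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()

    ncomp = int(min(ncomp, Xs.shape[1], Xs.shape[0] - 1))
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Xs, yc)

    W = pls.x_weights_  # (p, A), columns unit norm
    T = pls.x_scores_  # (n, A)
    q = pls.y_loadings_.ravel()  # (A,)
    ssy = q**2 * (T * T).sum(axis=0)  # variance of y explained per component
    # discard degenerate components (y already fully explained): zero weights
    live = (W**2).sum(axis=0) > 0
    W, T, q, ssy = W[:, live], T[:, live], q[live], ssy[live]
    ncomp = int(live.sum())
    p_feat = W.shape[0]
    wnorm2 = (W**2) / (W**2).sum(axis=0, keepdims=True)
    vip = np.sqrt(p_feat * (wnorm2 * ssy).sum(axis=1) / ssy.sum())

    return VIPResult(
        vip=pd.Series(vip, index=cols, name="vip"),
        n_components=ncomp,
        group_encoding=encoding,
        dropped=dropped,
    )


def select_vip(
    result: VIPResult, amounts: pd.DataFrame, threshold: float = 1.0
) -> tuple[list[str], pd.DataFrame]:
    """Species with VIP above the cutoff, plus their z-score matrix.

    Z-scores are computed per species across samples (mean 0, sd 1), the
    matrix conventionally drawn as a heatmap.  An empty selection is allowed.
    """
    selected = result.vip.index[result.vip > threshold].tolist()
    sub = amounts[selected]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    return selected, z
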