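"""One-way / two-way factorial ANOVA, Tukey HSD and compact letter displays.

The study design is a 3 x 3 factorial (zone x depth layer, 6 plots per
cell). Figures annotate each bar with two letter sets at alpha = 0.05:
capital letters compare depth layers within a zone, lowercase letters
compare zones within a depth layer; groups sharing a letter are not
significantly different under Tukey's HSD. Letters always reflect the
Tukey pairwise verdicts alone — the omnibus F is reported alongside but
does not gate the pairwise tests.

Normality (Shapiro-Wilk) and homogeneity (Levene) checks are advisory:
they log warnings and never block an analysis.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Data admit no F test (e.g. zero within-group variance)."""


@dataclass
class AnovaResult:
    terms: list[dict] = field(default_factory=list)
    residual: dict = field(default_factory=dict)
    n: int = 0

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = self.terms + [{"name": "residual", **self.residual}]
        return pd.DataFrame(rows)


@dataclass
class LetterAssignment:
    letters: dict[str, str]
    alpha: float = 0.05


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    labels = list(pd.unique(groups))
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return labels, samples


def check_assumptions(values, groups) -> None:
    """Advisory Shapiro-Wilk and Levene checks; warnings only."""
    labels, samples = _split_groups(values, groups)
    resid = np.concatenate([s - s.mean() for s in samples])
    if len(resid) >= 3 and np.ptp(resid) > 0:
        if stats.shapiro(resid).pvalue < 0.05:
            logger.warning("residuals depart from normality (Shapiro-Wilk p < 0.05)")
    try:
        if stats.levene(*samples).pvalue < 0.05:
            logger.warning("group variances heterogeneous (Levene p < 0.05)")
    except ValueError:
        pass


def one_way_anova(values, groups) -> AnovaResult:
    """Classical fixed-effects one-way decomposition."""
    labels, samples = _split_groups(values, groups)
    all_v = np.concatenate(samples)
    n = len(all_v)
    grand = all_v.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(labels) - 1
    df_w = n - len(labels)
    if ss_within <= 0:
        raise DegenerateDataError("degenerate: zero within-group variance")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        terms=[{"name": "group", "sum_sq": float(ss_between), "df": df_b,
                "F": float(F), "p": p}],
        residual={"sum_sq": float(ss_within), "df": df_w},
        n=n,
    )


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values.

    Columns: group1, group2, diff (mean1 - mean2), p, reject. Unbalanced
    groups use the Tukey-Kramer harmonic-mean form (with a warning).
    """
    labels, samples = _split_groups(values, groups)
    sizes = {len(s) for s in samples}
    if len(sizes) > 1:
        logger.warning("unbalanced groups %s: Tukey-Kramer adjustment in use",
                       sorted(sizes))
    if sum(((s - s.mean()) ** 2).sum() for s in samples) <= 0:
        raise DegenerateDataError("degenerate: zero within-group variance")
    res = stats.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        p = float(res.pvalue[i, j])
        rows.append({
            "group1": labels[i], "group2": labels[j],
            "diff": float(samples[i].mean() - samples[j].mean()),
            "p": p, "reject": p < alpha,
        })
    return pd.DataFrame(rows)


def compact_letters(pairwise: pd.DataFrame, alpha: float = 0.05) -> LetterAssignment:
    """Insertion-algorithm compact letter display.

    ``pairwise`` is the tukey_hsd frame (columns group1, group2, reject).
    Two groups share a letter iff their pair is not rejected. A pair listed
    twice with conflicting verdicts is an error.
    """
    verdicts: dict[frozenset, bool] = {}
    groups: list = []
    for _, row in pairwise.iterrows():
        pair = frozenset((row["group1"], row["group2"]))
        rej = bool(row["reject"])
        if pair in verdicts and verdicts[pair] != rej:
            raise ValueError(f"conflicting verdicts for pair {sorted(pair)}")
        verdicts[pair] = rej
        for g in (row["group1"], row["group2"]):
            if g not in groups:
                groups.append(g)
    # Insertion algorithm: start with one column holding every group; each
    # significant pair splits every column containing both members.
    columns: list[set] = [set(groups)]
    for pair, rej in verdicts.items():
        if not rej:
            continue
        a, b = tuple(pair)
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.extend([col - {a}, col - {b}])
            else:
                new_columns.append(col)
        # absorb columns contained in another
        columns = [
            c for i, c in enumerate(new_columns)
            if c and not any(
                c < d or (c == d and i > j) for j, d in enumerate(new_columns)
            )
        ]
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return LetterAssignment(letters=letters, alpha=alpha)


def two_way_anova(values, factor_zone, factor_depth) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction (Type II sums of squares)."""
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "zone": np.asarray(factor_zone).astype(str),
        "depth": np.asarray(factor_depth).astype(str),
    })
    cells = df.groupby(["zone", "depth"]).size()
    full = pd.MultiIndex.from_product(
        [df["zone"].unique(), df["depth"].unique()], names=["zone", "depth"]
    )
    empty = full.difference(cells.index)
    if len(empty) > 0:
        raise ValueError(f"empty cell(s): {list(empty)}")
    if df["zone"].nunique() < 2 or df["depth"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels")
    model = smf.ols("value ~ C(zone) * C(depth)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    name_map = {
        "C(zone)": "zone", "C(depth)": "depth", "C(zone):C(depth)": "zone:depth",
    }
    terms = []
    residual = {}
    for name, row in table.iterrows():
        if name == "Residual":
            residual = {"sum_sq": float(row["sum_sq"]), "df": int(row["df"])}
        else:
            terms.append({
                "name": name_map.get(name, name), "sum_sq": float(row["sum_sq"]),
                "df": int(row["df"]), "F": float(row["F"]),
                "p": float(row["PR(>F)"]),
            })
    return AnovaResult(terms=terms, residual=residual, n=len(df))


def run_study_contrasts(
    samples: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Letter tables per variable: capital = depths within zone, lowercase =
    zones within depth.

    Returns a long DataFrame (variable, zone, depth_layer, capital_letter,
    lowercase_letter). Factors with a single level are skipped with a
    logged warning (letters left empty).
    """
    df = samples
    if "fraction" in df.columns:
        df = df[df["fraction"] == "enzyme"]
    if variables is None:
        # design codes (distance, numeric depth) and aliases are not responses
        exclude = {"zone", "depth_layer", "plot_id", "fraction",
                   "mining_distance", "depth_cm", "x", "y"}
        variables = [c for c in df.columns
                     if c not in exclude and pd.api.types.is_numeric_dtype(df[c])]
    zones = list(pd.unique(df["zone"]))
    depths = list(pd.unique(df["depth_layer"]))
    rows = []
    for var in variables:
        caps: dict[tuple, str] = {}
        lows: dict[tuple, str] = {}
        if len(depths) >= 2:
            for zone in zones:
                sub = df[df["zone"] == zone]
                letters = compact_letters(
                    tukey_hsd(sub[var], sub["depth_layer"], alpha=alpha), alpha
                ).letters
                for depth, let in letters.items():
                    caps[(zone, depth)] = let.upper()
        else:
            logger.warning("single depth layer: capital-letter analysis skipped")
        if len(zones) >= 2:
            for depth in depths:
                sub = df[df["depth_layer"] == depth]
                letters = compact_letters(
                    tukey_hsd(sub[var], sub["zone"], alpha=alpha), alpha
                ).letters
                for zone, let in letters.items():
                    lows[(zone, depth)] = let
        else:
            logger.warning("single zone: lowercase-letter analysis skipped")
        for zone in zones:
            for depth in depths:
                rows.append({
                    "variable": var, "zone": zone, "depth_layer": depth,
                    "capital_letter": caps.get((zone, depth), ""),
                    "lowercase_letter": lows.get((zone, depth), ""),
                })
    return pd.DataFrame(rows)
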