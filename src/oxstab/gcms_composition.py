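"""GC–MS peak-table composition analysis.

Peak areas from total-ion-current chromatograms are normalised to the total
identified area per sample, compounds are binned by elemental formula into
four classes — monoterpenes C₁₀H₁₆, sesquiterpenes C₁₅H₂₄, and two
hydrocarbon-oxidation-product classes (oxygenated C₇₋₈ and oxygenated
C₂₀₊) — and class percentages are compared across ozonation categories
(A ambient, B 3 h, C 10 h) with classical one-way fixed-effects ANOVA.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

MONOTERPENE = "monoterpene_C10H16"
SESQUITERPENE = "sesquiterpene_C15H24"
OXID_C7_8 = "oxidation_C7-8HnOx"
OXID_C20P = "oxidation_C20+HnOx"
OTHER = "other"
CLASSES = (MONOTERPENE, SESQUITERPENE, OXID_C7_8, OXID_C20P, OTHER)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

PEAK_CSV_COLUMNS = ["sample_id", "species", "zone", "ozonation_category",
                    "retention_index", "compound", "formula", "area"]


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts from a plain elemental formula like ``C10H16O2``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula.strip()):
        raise ValidationError(f"unparseable elemental formula {formula!r}")
    counts: dict[str, int] = {}
    for element, number in _FORMULA_TOKEN.findall(formula.strip()):
        if element:
            counts[element] = counts.get(element, 0) + int(number or 1)
    return counts


def classify_compound(formula: str,
                      override: dict[str, str] | None = None) -> str:
    """Formula-driven class label with an optional per-formula override map."""
    if override and formula in override:
        return override[formula]
    counts = parse_formula(formula)
    c, h, o = counts.get("C", 0), counts.get("H", 0), counts.get("O", 0)
    if o == 0 and (c, h) == (10, 16):
        return MONOTERPENE
    if o == 0 and (c, h) == (15, 24):
        return SESQUITERPENE
    if o > 0 and 7 <= c <= 8:
        return OXID_C7_8
    if o > 0 and c >= 20:
        return OXID_C20P
    return OTHER


def normalise_peak_areas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percentages: 100 · area / Σ area over identified peaks."""
    if (table["area"] < 0).any():
        raise ValidationError("negative peak areas")
    totals = table.groupby("sample_id")["area"].transform("sum")
    if (table.groupby("sample_id")["area"].sum() <= 0).any():
        bad = table.groupby("sample_id")["area"].sum()
        raise ValidationError(
            f"zero total area for samples {list(bad[bad <= 0].index)}")
    out = table.copy()
    out["pct"] = 100.0 * out["area"] / totals
    return out


def aggregate_classes(table: pd.DataFrame,
                      override: dict[str, str] | None = None) -> pd.DataFrame:
    """Wide per-sample class-percentage profile (columns = classes).

    Percentages within each sample sum to 100 because the "other" class
    keeps every identified compound in the normalising total.
    """
    norm = normalise_peak_areas(table) if "pct" not in table.columns else table
    norm = norm.copy()
    norm["compound_class"] = [classify_compound(f, override)
                              for f in norm["formula"]]
    meta_cols = [c for c in ("species", "zone", "ozonation_category")
                 if c in norm.columns]
    wide = (norm.pivot_table(index=["sample_id", *meta_cols],
                             columns="compound_class", values="pct",
                             aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(CLASSES), fill_value=0.0)
            .reset_index())
    wide.columns.name = None
    return wide


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    group_ci: dict[str, tuple[float, float]]  # 0.95 CI of each group mean


def one_way_anova(groups: dict[str, np.ndarray],
                  conf_level: float = 0.95) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over ≥2 groups.

    Degenerate case: zero within-group variance with unequal means is
    reported as F = inf, p = 0.  Group-mean confidence intervals use each
    group's own t-based interval (the error-bar convention).
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    sizes = [len(a) for a in arrays.values()]
    if any(s < 1 for s in sizes) or sum(sizes) <= len(arrays):
        raise ValidationError("degenerate group sizes for ANOVA")
    k = len(arrays)
    n = sum(sizes)
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    means, cis = {}, {}
    for key, a in arrays.items():
        means[key] = float(a.mean())
        if len(a) > 1:
            half = stats.t.ppf(0.5 + conf_level / 2, len(a) - 1) * \
                a.std(ddof=1) / math.sqrt(len(a))
        else:
            half = math.nan
        cis[key] = (means[key] - half, means[key] + half)
    return AnovaResult(f=float(f), p=p, df_between=df_b, df_within=df_w,
                       group_means=means, group_ci=cis)


def class_anova_table(profiles: pd.DataFrame,
                      group_col: str = "ozonation_category",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-class ANOVA of composition percentages across categories."""
    rows = []
    for cls in CLASSES:
        groups = {str(g): sub[cls].to_numpy()
                  for g, sub in profiles.groupby(group_col)}
        res = one_way_anova(groups)
        rows.append({"compound_class": cls, "F": res.f, "p": res.p,
                     "df_between": res.df_between, "df_within": res.df_within,
                     "significant": res.p < alpha,
                     **{f"mean_{g}": m for g, m in res.group_means.items()}})
    return pd.DataFrame(rows)


def read_peak_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df
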