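"""Food-frequency-questionnaire trait derivation.

Categorical FFQ responses are converted to quantitative weekly/daily
frequencies, single items are combined into the standard food groups
(red meat, total fish, total fruits, total vegetables), and daily milk
volume is estimated from milk type and the number of cereal bowls and
coffee/tea cups it is added to.

The category->frequency mapping ships as a versioned YAML resource
(``data/ffq_conversion.yaml``) so it can be audited or overridden.
"""

from __future__ import annotations

import importlib.resources
import re
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "load_conversion_table",
    "convert_frequency",
    "estimate_milk",
    "compose_groups",
    "summarize_traits",
    "FFQError",
]

#: item -> conversion class for categorical items
ITEM_CLASSES = {
    "pork": "frequency",
    "beef": "frequency",
    "lamb": "frequency",
    "processed_meat": "frequency",
    "poultry": "frequency",
    "oily_fish": "frequency",
    "nonoily_fish": "frequency",
    "cheese": "frequency",
    "alcohol": "alcohol",
}

#: quantitative items passed through unchanged (value, unit)
QUANTITATIVE_ITEMS = (
    "fresh_fruit",
    "dried_fruit",
    "cooked_vegetables",
    "raw_vegetables",
    "coffee",
    "tea",
)

MILK_TYPES = ("never/rarely", "full cream", "semi-skimmed", "skimmed")

#: derived trait -> (constituent items, combiner)
GROUP_FORMULAS = {
    "red_meat": ("pork", "beef", "lamb"),
    "total_fish": ("oily_fish", "nonoily_fish"),
    "total_fruit": ("fresh_fruit", "dried_fruit"),
    "total_vegetables": ("cooked_vegetables", "raw_vegetables"),
}

#: units of the derived traits
TRAIT_UNITS = {
    "red_meat": "times/week",
    "processed_meat": "times/week",
    "poultry": "times/week",
    "total_fish": "times/week",
    "milk": "mL/day",
    "cheese": "times/week",
    "total_fruit": "servings/day",
    "total_vegetables": "servings/day",
    "coffee": "cups/day",
    "tea": "cups/day",
    "alcohol": "times/week",
}


class FFQError(ValueError):
    """Raised for unknown response labels or invalid FFQ inputs."""


def _normalize(label: str) -> str:
    # case-insensitive match after whitespace collapse; en/em dashes -> hyphen
    s = str(label).strip().lower()
    s = s.replace("–", "-").replace("—", "-")
    s = re.sub(r"\s*-\s*", "-", s)
    return re.sub(r"\s+", " ", s)


@lru_cache(maxsize=4)
def load_conversion_table(path: str | None = None) -> dict:
    """Load the category->frequency conversion table (YAML).

    Returns a dict with normalized response labels; ``path=None`` loads the
    packaged version-1 table.
    """
    if path is None:
        ref = importlib.resources.files("dietmr").joinpath("data/ffq_conversion.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {"version": raw.get("version"), "classes": {}, "missing": set()}
    for cls, spec in raw["classes"].items():
        table["classes"][cls] = {
            "unit": spec["unit"],
            "responses": {_normalize(k): float(v) for k, v in spec["responses"].items()},
        }
    table["missing"] = {_normalize(m) for m in raw.get("missing_responses", [])}
    return table


def convert_frequency(item_class: str, response: str, table: dict | None = None) -> float:
    """Map one categorical response to its numeric frequency (times/week).

    ``item_class`` is ``"frequency"`` (meat/fish/cheese scale) or
    ``"alcohol"``.  "Do not know"/"prefer not to answer" return NaN.
    Unknown labels raise :class:`FFQError` naming the class and label.
    """
    table = table or load_conversion_table()
    if item_class not in table["classes"]:
        raise FFQError(f"unknown item class {item_class!r}")
    key = _normalize(response)
    if key in table["missing"]:
        return float("nan")
    responses = table["classes"][item_class]["responses"]
    if key not in responses:
        raise FFQError(f"unknown response {response!r} for item class {item_class!r}")
    return responses[key]


def category_values(item_class: str, table: dict | None = None) -> np.ndarray:
    """Sorted numeric values of all categories of an item class."""
    table = table or load_conversion_table()
    return np.array(sorted(table["classes"][item_class]["responses"].values()))


def estimate_milk(milk_type: str, cereal_bowls: float, coffee_cups: float, tea_cups: float) -> float:
    """Estimate daily milk volume (mL/day).

    milk = 100*cereal bowls + 25*coffee cups + 35*tea cups, and 0 for
    never/rarely consumers regardless of the counts.
    """
    allowed = {_normalize(t).replace(" ", ""): t for t in MILK_TYPES}
    mt_key = _normalize(milk_type).replace(" ", "")
    if mt_key not in allowed:
        raise FFQError(f"unknown milk type {milk_type!r}; expected one of {MILK_TYPES}")
    if any(pd.isna(c) for c in (cereal_bowls, coffee_cups, tea_cups)):
        return float("nan")
    if min(cereal_bowls, coffee_cups, tea_cups) < 0:
        raise FFQError("cup/bowl counts must be non-negative")
    if allowed[mt_key] == "never/rarely":
        return 0.0
    return 100.0 * cereal_bowls + 25.0 * coffee_cups + 35.0 * tea_cups


def compose_groups(items: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine single food items into the derived trait table.

    ``items`` holds one row per participant with numeric columns for single
    items (categorical items already converted to times/week).  Composites:

    * red meat   = pork + beef + lamb                 (times/week)
    * total fish = oily + non-oily fish               (times/week)
    * total fruit = fresh + 0.5 * dried fruit         (servings/day)
    * total vegetables = cooked + raw                 (servings/day)

    A composite is missing iff any constituent is missing.  Returns the
    derived trait table and a per-trait missingness report (n_missing,
    pct_missing).
    """
    out = pd.DataFrame(index=items.index)
    for trait, parts in GROUP_FORMULAS.items():
        for p in parts:
            if p not in items.columns:
                raise FFQError(f"missing constituent column {p!r} for {trait!r}")
        if trait == "total_fruit":
            vals = items["fresh_fruit"] + 0.5 * items["dried_fruit"]
        else:
            vals = items[list(parts)].sum(axis=1, skipna=False)
        out[trait] = vals
    for col in ("processed_meat", "poultry", "cheese", "milk", "coffee", "tea", "alcohol"):
        if col in items.columns:
            out[col] = items[col]
    report = pd.DataFrame(
        {
            "n_missing": out.isna().sum(),
            "pct_missing": 100.0 * out.isna().mean(),
        }
    )
    return out, report


def summarize_traits(
    traits: pd.DataFrame, max_shapiro_n: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Descriptive summary per trait with a normality-aware location/spread.

    Shapiro-Wilk is evaluated on a seeded random subsample capped at
    ``max_shapiro_n`` (the test is over-powered and undefined at biobank
    sample sizes).  Normal-looking traits (p >= 0.05) report mean +- sd,
    otherwise median and interquartile range.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for col in traits.columns:
        x = traits[col].dropna().to_numpy(float)
        if x.size < 3:
            raise FFQError(f"trait {col!r} has fewer than 3 non-missing values")
        if np.ptp(x) == 0:
            raise FFQError(f"trait {col!r} is constant; normality test undefined")
        sub = x if x.size <= max_shapiro_n else rng.choice(x, max_shapiro_n, replace=False)
        sw_p = float(stats.shapiro(sub).pvalue)
        normal = sw_p >= 0.05
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {
                "trait": col,
                "n": int(x.size),
                "n_missing": int(traits[col].isna().sum()),
                "pct_missing": 100.0 * float(traits[col].isna().mean()),
                "shapiro_p": sw_p,
                "normal": normal,
                "location": float(np.mean(x)) if normal else float(med),
                "spread_low": float(np.mean(x) - np.std(x, ddof=1)) if normal else float(q1),
                "spread_high": float(np.mean(x) + np.std(x, ddof=1)) if normal else float(q3),
                "summary": (
                    f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"
                    if normal
                    else f"{med:.2f} ({q1:.2f}–{q3:.2f})"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def convert_items(responses: pd.DataFrame, table: dict | None = None) -> pd.DataFrame:
    """Convert a raw FFQ response table to numeric item values.

    Columns listed in :data:`ITEM_CLASSES` are converted through the
    category table; quantitative columns are coerced to float and pass
    through.
    """
    table = table or load_conversion_table()
    out = pd.DataFrame(index=responses.index)
    for col in responses.columns:
        if col in ITEM_CLASSES:
            cls = ITEM_CLASSES[col]
            out[col] = [
                convert_frequency(cls, v, table) if pd.notna(v) else np.nan
                for v in responses[col]
            ]
        else:
            out[col] = pd.to_numeric(responses[col], errors="coerce")
    return out
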