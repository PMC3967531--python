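"""Group statistics on Fisher-Z connectivity: t-tests, Bonferroni control,
hemisphere-interaction regression, cognition regressions, effect sizes.

The family of hemisphere-resolved tests has m = 90 members (45 pairs x 2
hemispheres), so the Bonferroni threshold at alpha = 0.05 is 0.05/90 ~
0.00056; the interhemispheric-averaged family has m = 45.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .connectivity import ConnectivityRecord, inverse_fisher_z

COGNITION_FACTORS = ("memory", "speed", "general_fluid", "vocabulary")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha/m controlling family-wise error at alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _family_matrix(records: list[ConnectivityRecord], family: str, group: str) -> pd.DataFrame:
    rows = [r.z_values(family) for r in records if r.group == group]
    if not rows:
        raise ValueError(f"no subjects in group {group!r}")
    return pd.DataFrame(rows)


def cohens_d(young: np.ndarray, elder: np.ndarray) -> float:
    """(mean_young - mean_elder) / pooled SD."""
    young = np.asarray(young, dtype=float)
    elder = np.asarray(elder, dtype=float)
    if len(young) < 2 or len(elder) < 2:
        raise ValueError("need at least 2 subjects per group")
    ny, ne = len(young), len(elder)
    pooled = np.sqrt(
        ((ny - 1) * young.var(ddof=1) + (ne - 1) * elder.var(ddof=1)) / (ny + ne - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((young.mean() - elder.mean()) / pooled)


def group_compare(
    records: list[ConnectivityRecord],
    family: str = "both",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests on Fisher-Z values for every pair in a family.

    ``family`` is ``left``, ``right``, ``both`` (hemisphere-resolved, the
    90-test family) or ``avg`` (the 45-test family).  The Bonferroni
    threshold uses the size of the whole family tested together.  Group
    means are reported on the Z scale and back-transformed for display.
    The default is the pooled-variance (Student) test; ``equal_var=False``
    switches to Welch.
    """
    fam_map = {"left": ["L"], "right": ["R"], "both": ["L", "R"], "avg": ["avg"]}
    if family not in fam_map:
        raise ValueError(f"family must be one of {sorted(fam_map)}")
    hemis = fam_map[family]
    frames = []
    for hemi in hemis:
        young = _family_matrix(records, hemi, "young")
        elder = _family_matrix(records, hemi, "elder")
        if len(young) < 2 or len(elder) < 2:
            raise ValueError("need at least 2 subjects per group")
        t, p = sps.ttest_ind(young, elder, axis=0, equal_var=equal_var)
        frame = pd.DataFrame(
            {
                "pair": young.columns,
                "hemisphere": hemi,
                "mean_young": young.mean(axis=0).to_numpy(),
                "mean_elder": elder.mean(axis=0).to_numpy(),
                "t_statistic": t,
                "p_value": p,
                "effect_size": [
                    cohens_d(young[c].to_numpy(), elder[c].to_numpy()) for c in young.columns
                ],
            }
        )
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    m = len(table)
    threshold = bonferroni_threshold(alpha, m)
    table["mean_r_young"] = inverse_fisher_z(table["mean_young"].to_numpy())
    table["mean_r_elder"] = inverse_fisher_z(table["mean_elder"].to_numpy())
    table["sig_uncorrected"] = table["p_value"] < alpha
    table["sig_bonferroni"] = table["p_value"] < threshold
    table["direction"] = np.where(
        table["mean_elder"] > table["mean_young"], "increase", "decrease"
    )
    table.attrs["n_tests"] = m
    table.attrs["alpha"] = alpha
    table.attrs["bonferroni_threshold"] = threshold
    return table


def hemisphere_interaction(records: list[ConnectivityRecord], pair: str) -> pd.DataFrame:
    """OLS of z ~ group + hemisphere + group x hemisphere for one pair.

    Each subject contributes two stacked observations (left and right),
    with hemisphere coded 0 = L / 1 = R and group coded 0 = young /
    1 = elder.  A significant interaction means the age-group difference
    in connectivity differs between hemispheres (a unilateral effect).
    Returns a coefficient table with two-sided p-values.
    """
    rows = []
    for rec in records:
        zl = rec.z_values("L")
        zr = rec.z_values("R")
        if pair not in zl.index or pair not in zr.index:
            raise ValueError(f"pair {pair!r} missing a hemisphere for {rec.subject_id}")
        g = 1.0 if rec.group == "elder" else 0.0
        rows.append({"z": zl[pair], "group": g, "hemisphere": 0.0})
        rows.append({"z": zr[pair], "group": g, "hemisphere": 1.0})
    data = pd.DataFrame(rows)
    data["interaction"] = data["group"] * data["hemisphere"]
    design = sm.add_constant(data[["group", "hemisphere", "interaction"]])
    fit = sm.OLS(data["z"], design).fit()
    return pd.DataFrame(
        {"coef": fit.params, "std_err": fit.bse, "t": fit.tvalues, "p_value": fit.pvalues}
    )


def cognition_regression(
    z: pd.Series,
    cognition: pd.DataFrame,
    factor: str,
    group: str,
) -> dict:
    """Within-group OLS of a cognitive factor on connectivity, age-adjusted.

    ``z`` maps subject id to the pair's Fisher-Z value; ``cognition`` has
    one row per subject with columns ``group``, ``age`` and the four
    factor scores.  Fits factor ~ intercept + z + age inside the given
    group and returns the z slope with its two-sided p-value.
    """
    if factor not in cognition.columns:
        raise ValueError(f"unknown factor {factor!r}")
    sub = cognition[cognition["group"] == group]
    if len(sub) < 4:
        raise ValueError("need at least 4 subjects in the group")
    zg = z.loc[sub.index]
    if np.ptp(zg.to_numpy()) == 0:
        raise ValueError("connectivity is constant within the group")
    design = sm.add_constant(pd.DataFrame({"z": zg, "age": sub["age"]}))
    fit = sm.OLS(sub[factor], design).fit()
    return {
        "slope": float(fit.params["z"]),
        "p_value": float(fit.pvalues["z"]),
        "n": int(len(sub)),
    }


def effect_size(records: list[ConnectivityRecord], pair: str, hemisphere: str) -> float:
    """Cohen's d between groups for one pair in one hemisphere family."""
    young = _family_matrix(records, hemisphere, "young")[pair].to_numpy()
    elder = _family_matrix(records, hemisphere, "elder")[pair].to_numpy()
    return cohens_d(young, elder)
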