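"""Broad-sense heritability screening from F1/F2 variance comparison.

F1 animals of an intercross are genetically identical, so their phenotypic
variance is purely environmental; the F2 cohort adds segregating genetic
variance.  H² = 1 − Var(F1)/Var(F2) (sample variances) therefore estimates
the broad-sense heritability, and phenotypes are carried into QTL mapping
when H² strictly exceeds a criterion (40% in the screening design this
package follows).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HERITABILITY_CRITERION_PERCENT = 40.0


def estimate_heritability(values_f1: np.ndarray, values_f2: np.ndarray) -> float:
    """H² in percent: 100 · max(0, 1 − Var(F1)/Var(F2))."""
    f1 = np.asarray(values_f1, float)
    f2 = np.asarray(values_f2, float)
    if len(f1) < 2 or len(f2) < 2:
        raise ValueError("need at least 2 values in each cohort")
    v1 = float(np.var(f1, ddof=1))
    v2 = float(np.var(f2, ddof=1))
    if v2 == 0:
        raise ValueError("zero F2 variance: heritability undefined")
    return 100.0 * max(0.0, 1.0 - v1 / v2)


def select_phenotypes(
    phenotypes_f1: pd.DataFrame,
    phenotypes_f2: pd.DataFrame,
    criterion_percent: float = HERITABILITY_CRITERION_PERCENT,
) -> pd.DataFrame:
    """Phenotypes whose H² strictly exceeds the criterion.

    Returns a DataFrame (phenotype, h2_percent, selected) for every shared
    column; raises when the F1 cohort is missing (environmental variance
    would be unestimable).
    """
    if phenotypes_f1 is None or len(phenotypes_f1) == 0:
        raise ValueError("F1 cohort missing: environmental variance unestimable")
    rows = []
    for col in phenotypes_f2.columns:
        if col not in phenotypes_f1.columns:
            continue
        f1 = phenotypes_f1[col].dropna().to_numpy()
        f2 = phenotypes_f2[col].dropna().to_numpy()
        try:
            h2 = estimate_heritability(f1, f2)
        except ValueError:
            continue
        rows.append(dict(phenotype=col, h2_percent=h2,
                         selected=h2 > criterion_percent))
    return pd.DataFrame(rows)
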