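"""Differential-expression scoring shared by the annotation-based test and
segment scoring.

The P score is the probability of differential expression, defined as one
minus the two-sided p-value of a Welch (unequal-variance) two-sample t-test
comparing all pooled probe x replicate log2 intensities of the two
conditions.  The log2 fold change is mean(treated) - mean(reference).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st


def welch_de(reference: np.ndarray, treated: np.ndarray) -> tuple[float, float]:
    """Return ``(p_score, log2_fold_change)`` for two pooled value vectors.

    Degenerate inputs are defined rather than NaN: if both groups have zero
    variance, the P score is 0 for equal means (no evidence of change) and
    1 for unequal means (an exact, noiseless shift).
    """
    reference = np.asarray(reference, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if reference.size < 2 or treated.size < 2:
        raise ValueError("need at least 2 values per condition")
    fc = float(np.mean(treated) - np.mean(reference))
    var_r = float(np.var(reference, ddof=1))
    var_t = float(np.var(treated, ddof=1))
    if var_r == 0.0 and var_t == 0.0:
        return (0.0 if fc == 0.0 else 1.0), fc
    t = _st.ttest_ind(treated, reference, equal_var=False)
    return 1.0 - float(t.pvalue), fc
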