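"""Independent reference implementations used only as test oracles."""

import numpy as np


def icc_anova_oracle(y_true, y_pred):
    """Independent two-way-ANOVA route: mean squares from an OLS fit of
    score ~ instance + observer, combined into the single-rater
    absolute-agreement ICC."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n = len(y_true)
    df = pd.DataFrame({
        "instance": np.tile(np.arange(n), 2).astype(str),
        "observer": np.repeat(["a", "b"], n),
        "score": np.concatenate([np.asarray(y_true), np.asarray(y_pred)]),
    })
    fit = ols("score ~ C(instance) + C(observer)", df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    ms_i = aov.loc["C(instance)", "sum_sq"] / aov.loc["C(instance)", "df"]
    ms_o = aov.loc["C(observer)", "sum_sq"] / aov.loc["C(observer)", "df"]
    ms_e = aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"]
    O = 2
    return (ms_i - ms_e) / (ms_i + (O - 1) * ms_e + O * (ms_o - ms_e) / n)
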