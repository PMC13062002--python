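"""Published keratoconus MR effect estimates used for reporting checks.

The keratoconus causal-inference literature reports, per exposure and
method, the estimate on the log-odds scale (ln(OR)) and its standard
error, with odds ratios and 95% confidence intervals derived from them.
This module carries those published (ln(OR), SE) pairs as *inputs* so the
package's reporting transforms (:func:`mrkit.estimators.to_odds_ratio`,
:func:`mrkit.estimators.two_sided_p`) can be checked against, and used to
regenerate, the published OR/CI/p values.

Exposure effect directions: serum glucose (per mmol/L) is protective;
atopy-related exposures and circulating eosinophil count increase
keratoconus risk.
"""

from __future__ import annotations

import pandas as pd

from .estimators import to_odds_ratio, two_sided_p

#: (exposure, source cohort, method, ln_or, se) as published.
PUBLISHED_ESTIMATES: tuple[tuple[str, str, str, float, float], ...] = (
    ("glucose", "UK Biobank", "Simple median", -0.8639, 0.3095),
    ("glucose", "UK Biobank", "IVW", -0.7220, 0.2013),
    ("glucose", "UK Biobank", "MR-Egger", -0.7010, 0.3015),
    ("glucose", "UK Biobank", "(intercept)", -0.0006, 0.0059),
    ("glucose", "MAGIC", "Simple median", -0.6747, 0.2527),
    ("glucose", "MAGIC", "IVW", -0.8434, 0.1993),
    ("glucose", "MAGIC", "MR-Egger", -0.9426, 0.3716),
    ("glucose", "MAGIC", "(intercept)", 0.0030, 0.0095),
    ("eosinophil count", "blood-cell GWAS", "Simple median", 0.455, 0.117),
    ("eosinophil count", "blood-cell GWAS", "IVW", 0.353, 0.084),
    ("eosinophil count", "blood-cell GWAS", "MR-Egger", 0.218, 0.164),
    ("eosinophil count", "blood-cell GWAS", "(intercept)", 0.005, 0.005),
    ("adult-onset asthma", "atopy GWAS", "Simple median", 0.013, 0.125),
    ("adult-onset asthma", "atopy GWAS", "IVW", 0.014, 0.112),
    ("adult-onset asthma", "atopy GWAS", "MR-Egger", -0.100, 0.375),
    ("adult-onset asthma", "atopy GWAS", "(intercept)", 0.009, 0.030),
    ("all atopic diseases combined", "atopy GWAS", "Simple median", 0.633, 0.122),
    ("all atopic diseases combined", "atopy GWAS", "IVW", 0.610, 0.096),
    ("all atopic diseases combined", "atopy GWAS", "MR-Egger", 0.401, 0.261),
    ("all atopic diseases combined", "atopy GWAS", "(intercept)", 0.011, 0.013),
    ("childhood asthma", "atopy GWAS", "Simple median", 0.050, 0.055),
    ("childhood asthma", "atopy GWAS", "IVW", 0.042, 0.045),
    ("childhood asthma", "atopy GWAS", "MR-Egger", -0.053, 0.107),
    ("childhood asthma", "atopy GWAS", "(intercept)", 0.013, 0.013),
    ("non-asthma allergic disease", "allergy GWAS", "Simple median", 0.476, 0.093),
    ("non-asthma allergic disease", "allergy GWAS", "IVW", 0.518, 0.077),
    ("non-asthma allergic disease", "allergy GWAS", "MR-Egger", 0.584, 0.192),
    ("non-asthma allergic disease", "allergy GWAS", "(intercept)", -0.004, 0.011),
    ("asthma", "asthma GWAS", "Simple median", 0.312, 0.118),
    ("asthma", "asthma GWAS", "IVW", 0.263, 0.091),
    ("asthma", "asthma GWAS", "MR-Egger", -0.169, 0.303),
    ("asthma", "asthma GWAS", "(intercept)", 0.053, 0.035),
)

#: Number of IVW analyses in the published multi-exposure design, used for
#: its Bonferroni accounting (0.05/12).
PUBLISHED_N_TESTS = 12


def published_or_table(confidence: float = 0.95) -> pd.DataFrame:
    """Recompute OR, CI and p for every published (ln(OR), SE) pair.

    Intercept rows describe the pleiotropy estimate, not an exposure
    effect, so their OR columns are left as NaN.
    """
    rows = []
    for exposure, source, method, ln_or, se in PUBLISHED_ESTIMATES:
        pvalue = two_sided_p(ln_or, se)
        if method == "(intercept)":
            or_point = ci_low = ci_high = float("nan")
        else:
            or_point, ci_low, ci_high = to_odds_ratio(ln_or, se, confidence)
        rows.append(
            {
                "exposure": exposure,
                "source": source,
                "method": method,
                "ln_or": ln_or,
                "se": se,
                "or": or_point,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "pvalue": pvalue,
            }
        )
    return pd.DataFrame(rows)
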