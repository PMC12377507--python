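"""Shared helper for the example scripts: the screening cascade in one call."""

from uaiscore import (
    interaction_screen,
    select_marker_genes,
    univariate_survival_screen,
)


def screen_markers(expr, clin, training_ids, alpha=0.05):
    dfs = univariate_survival_screen(expr, clin, "DFS", training_ids)
    os_ = univariate_survival_screen(expr, clin, "OS", training_ids)
    survivors = dfs.index[
        (dfs["p"] < alpha) & (os_["p"] < alpha) & dfs["converged"] & os_["converged"]
    ].tolist()
    records = interaction_screen(expr, clin, survivors, training_ids, alpha)
    return select_marker_genes(records)
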