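"""Wave-to-wave movement between worry groups.

For linked panelists classifiable in both waves, builds the 3x3 transition
count matrix over (Unworried, Functional, Dysfunctional) in fixed order, its
row-stochastic probability matrix, and the stability share (fraction who stay
in the same group = trace / linked n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .classify import GROUP_LABELS, DichotomyConfig, WorryGroup, classify_table
from .survey_io import PanelTable


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # 3x3 integer, rows = wave-2 group, cols = wave-3 group
    probabilities: pd.DataFrame  # row-stochastic; all-NaN row where count row is 0
    stability_share: float
    n_linked: int
    n_excluded: int  # linked but unclassifiable in at least one wave

    @property
    def mover_share(self) -> float:
        return 1.0 - self.stability_share


def transition_matrix_from_labels(g2: pd.Series, g3: pd.Series) -> TransitionMatrix:
    """Transition matrix from aligned wave-2 / wave-3 group label vectors."""
    g2 = g2.astype("string")
    g3 = g3.astype("string")
    classifiable = g2.isin(GROUP_LABELS) & g3.isin(GROUP_LABELS)
    n_excluded = int((~classifiable).sum())
    g2c, g3c = g2[classifiable], g3[classifiable]
    n_linked = int(classifiable.sum())
    if n_linked == 0:
        raise ValueError("no linked respondents classifiable in both waves")
    counts = (
        pd.crosstab(g2c, g3c)
        .reindex(index=GROUP_LABELS, columns=GROUP_LABELS, fill_value=0)
        .astype(int)
    )
    counts.index.name = "wave2_group"
    counts.columns.name = "wave3_group"
    row_sums = counts.sum(axis=1)
    probs = counts.div(row_sums.replace(0, np.nan), axis=0)
    stability = float(np.trace(counts.to_numpy())) / n_linked
    return TransitionMatrix(
        counts=counts,
        probabilities=probs,
        stability_share=stability,
        n_linked=n_linked,
        n_excluded=n_excluded,
    )


def transitions(panel: PanelTable, cfg: DichotomyConfig = DichotomyConfig()) -> TransitionMatrix:
    """Classify both waves of a linked panel and tabulate group movement.

    Respondents not present or not classifiable in both waves are excluded
    from the matrix; their count is reported in ``n_excluded`` (plus the
    linkage counts on the panel itself).
    """
    both = panel.both_waves_ids
    w2 = classify_table(panel.wave2.set_index("respondent_id").loc[both].reset_index(), cfg)
    w3 = classify_table(panel.wave3.set_index("respondent_id").loc[both].reset_index(), cfg)
    g2 = w2.set_index("respondent_id")["worry_group"]
    g3 = w3.set_index("respondent_id")["worry_group"]
    return transition_matrix_from_labels(g2, g3.loc[g2.index])


def sankey_table(matrix: TransitionMatrix, drop_zero: bool = False) -> pd.DataFrame:
    """Long-format flow table (source, target, count, probability), source-major.

    A tabular stand-in for an alluvial/Sankey diagram; flows sum to n_linked.
    """
    rows = []
    for src in GROUP_LABELS:
        for dst in GROUP_LABELS:
            c = int(matrix.counts.loc[src, dst])
            if drop_zero and c == 0:
                continue
            p = matrix.probabilities.loc[src, dst]
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "count": c,
                    "probability": float(p) if pd.notna(p) else np.nan,
                }
            )
    return pd.DataFrame(rows)
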