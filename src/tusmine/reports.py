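"""Resource-style report tables.

Row and column labels mirror the published resource tables for the SSR
search summary and the variant classification matrix; every total is
computed from the components, never copied in.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .markers import CascadeResult
from .ssr import SSRSearchSummary
from .variants import ClassificationMatrix

SSR_SUMMARY_ROWS = (
    ("Total number of TUSs examined", "n_sequences"),
    ("Total size of examined sequences (bp)", "total_bp"),
    ("Total number of identified SSRs", "n_ssrs"),
    ("Number of SSR containing sequences", "n_sequences_with_ssr"),
    ("Number of sequences containing >1 SSR", "n_sequences_with_multiple"),
    ("Number of SSRs present in compound formation", "n_compound"),
    ("Mono-nucleotide repeats", 1),
    ("Di-nucleotide repeats", 2),
    ("Tri-nucleotide repeats", 3),
    ("Tetra-nucleotide repeats", 4),
    ("Penta-nucleotide repeats", 5),
    ("Hexa-nucleotide repeats", 6),
)


def ssr_summary_table(summary: SSRSearchSummary) -> pd.DataFrame:
    rows = []
    for label, key in SSR_SUMMARY_ROWS:
        value = (
            summary.per_unit_length.get(key, 0)
            if isinstance(key, int)
            else getattr(summary, key)
        )
        rows.append({"Statistic": label, "Value": int(value)})
    return pd.DataFrame(rows)


def write_ssr_summary(summary: SSRSearchSummary, path: str | Path) -> None:
    ssr_summary_table(summary).to_csv(path, sep="\t", index=False)


def write_classification_matrix(matrix: ClassificationMatrix, path: str | Path) -> None:
    matrix.to_tsv(path)


def de_accounting_json(accounting: Mapping[str, int], path: str | Path) -> None:
    """DE set bookkeeping: fold-change set, R set, overlap, union."""
    with open(path, "w") as fh:
        json.dump(dict(accounting), fh, indent=1, sort_keys=True)


def cascade_accounting_table(result: CascadeResult) -> pd.DataFrame:
    n1, n2, n3, n4 = result.counts
    return pd.DataFrame(
        [
            {"Stage": "Similarity in all six species", "Surviving": n1},
            {"Stage": "Identical functional annotation", "Surviving": n2},
            {"Stage": "After paralog removal", "Surviving": n3},
            {"Stage": "After prior-COS exclusion", "Surviving": n4},
        ]
    )


def write_cascade_accounting(result: CascadeResult, path: str | Path) -> None:
    cascade_accounting_table(result).to_csv(path, sep="\t", index=False)
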