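"""Diagnostic-character extraction for population/species diagnosis.

A character-based complement to distance barcoding: an alignment position
diagnoses a group when some nucleotide state occurring in that group is
absent from every member of every other group. A *pure* diagnostic is fixed
in its group (confidence 1.0); a *private* diagnostic occurs in only part
of the group (confidence = within-group frequency). Only simple
(single-position) characters are considered. Gaps and ambiguity codes are
treated as missing and never count as diagnostic states; a member carrying
a gap at a position also prevents any state there from being pure for its
group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distances import _DECODE, LabeledAlignment

__all__ = [
    "find_diagnostics",
    "site_classes",
    "diagnostic_site_fraction",
    "classify_query",
]


def find_diagnostics(aln: LabeledAlignment) -> pd.DataFrame:
    """Scan every (position, group, state) triple for diagnostic characters.

    Returns a character-level table with columns ``group``, ``pos``
    (1-based), ``state``, ``conf`` and ``klass`` (pure|private), sorted by
    (group, pos). A single site may diagnose several groups; use
    :func:`site_classes` for the distinct-site view.
    """
    groups = sorted(set(aln.labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to extract diagnostics")
    codes = aln.codes()  # (n, L), -1 = missing
    n, length = codes.shape
    labels = np.array(aln.labels)

    # counts[g, state, pos]
    counts = np.zeros((len(groups), 4, length), dtype=int)
    sizes = np.zeros(len(groups), dtype=int)
    for gi, g in enumerate(groups):
        sub = codes[labels == g]
        sizes[gi] = sub.shape[0]
        for state in range(4):
            counts[gi, state] = (sub == state).sum(axis=0)

    total = counts.sum(axis=0)  # (4, L)
    rows = []
    for gi, g in enumerate(groups):
        present = counts[gi] > 0
        absent_outside = (total - counts[gi]) == 0
        diag = present & absent_outside  # (4, L)
        for state, pos in zip(*np.nonzero(diag)):
            conf = counts[gi, state, pos] / sizes[gi]
            rows.append(
                {
                    "group": g,
                    "pos": int(pos) + 1,
                    "state": _DECODE[state],
                    "conf": float(conf),
                    "klass": "pure" if counts[gi, state, pos] == sizes[gi] else "private",
                }
            )
    table = pd.DataFrame(rows, columns=["group", "pos", "state", "conf", "klass"])
    return table.sort_values(["group", "pos"], kind="stable").reset_index(drop=True)


def site_classes(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct-site view: each diagnostic site classed pure or private.

    A site counts as pure if it carries at least one pure character for any
    group, else private. This is the site-level count that, together with
    the character-level table, reconciles "sites diagnosed" against the
    (larger) number of character rows.
    """
    if table.empty:
        return pd.DataFrame(columns=["pos", "klass"])
    rows = []
    for pos, sub in table.groupby("pos"):
        klass = "pure" if (sub["klass"] == "pure").any() else "private"
        rows.append({"pos": int(pos), "klass": klass})
    return pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)


def diagnostic_site_fraction(table: pd.DataFrame, aln_length: int) -> float:
    """Percentage of alignment positions carrying >= 1 diagnostic character.

    100 * (#distinct diagnostic positions) / aln_length, rounded to 1 dp.
    """
    if aln_length < 1:
        raise ValueError("alignment length must be >= 1")
    n_sites = 0 if table.empty else table["pos"].nunique()
    return round(100.0 * n_sites / aln_length, 1)


def classify_query(
    seq: str, table: pd.DataFrame, aln_length: int | None = None,
    margin: float = 0.1, min_score: float = 0.5,
) -> tuple[str | None, dict[str, float]]:
    """Assign a query sequence to a group by its pure diagnostic characters.

    Score per group = fraction of that group's pure characters matched by
    the query. The argmax group is assigned when its score exceeds
    ``min_score`` and beats the runner-up by ``margin``; otherwise the query
    is left unassigned (None). The query must be aligned to the same
    coordinates as the table's alignment.
    """
    if aln_length is not None and len(seq) != aln_length:
        raise ValueError(f"query length {len(seq)} != alignment length {aln_length}")
    pure = table[table["klass"] == "pure"]
    seq = seq.upper()
    scores: dict[str, float] = {}
    for g, sub in pure.groupby("group"):
        if aln_length is None and (sub["pos"] > len(seq)).any():
            raise ValueError("query shorter than diagnostic positions require")
        matched = sum(1 for _, r in sub.iterrows() if seq[r["pos"] - 1] == r["state"])
        scores[g] = matched / len(sub)
    for g in table["group"].unique():
        scores.setdefault(g, 0.0)
    if not scores:
        return None, scores
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top_group, top = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0.0
    if top > min_score and top - runner >= margin:
        return top_group, scores
    return None, scores
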