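"""Cluster-by-biological-function over-representation summary.

After selection, variables (e.g. O-PTM events) are grouped by temporal
cluster and by annotated biological function. Each (cluster, function) cell
counts events and distinct host proteins and is tested for over-representation
with a hypergeometric tail at the protein level (a protein carrying several
modified sites counts once, avoiding pseudo-replication); Benjamini–Hochberg
adjustment across all cells flags significant bubbles (q < 0.05). The
resulting table drives the usual bubble plot: radius = event count, label =
protein count, star = significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster import ClusteringResult
from .errors import ParameterError
from .jackstraw import SelectionReport

SIGNIFICANCE_Q = 0.05


@dataclass
class AnnotationMap:
    """variable -> host protein and protein -> biological-function terms."""

    variable_to_protein: dict = field(default_factory=dict)
    protein_to_functions: dict = field(default_factory=dict)

    def functions_of_variable(self, variable_id) -> set:
        protein = self.variable_to_protein.get(variable_id)
        if protein is None:
            return set()
        return set(self.protein_to_functions.get(protein, set()))

    @property
    def all_functions(self) -> set:
        out = set()
        for fns in self.protein_to_functions.values():
            out |= set(fns)
        return out


def read_annotation_map(variable_protein_path, protein_function_path,
                        delimiter="\t") -> AnnotationMap:
    """Load the two-file annotation: variable->protein and protein->function."""
    vp = pd.read_csv(variable_protein_path, sep=delimiter, header=None,
                     names=["variable_id", "protein_id"], dtype=str,
                     comment="#")
    pf = pd.read_csv(protein_function_path, sep=delimiter, header=None,
                     names=["protein_id", "function"], dtype=str, comment="#")
    v2p = dict(zip(vp["variable_id"], vp["protein_id"]))
    p2f = {}
    for protein, fn in zip(pf["protein_id"], pf["function"]):
        p2f.setdefault(protein, set()).add(fn)
    return AnnotationMap(v2p, p2f)


def hypergeometric_test(overlap: int, set_size: int, draw_size: int,
                        universe: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeom(universe, set_size, draw_size)."""
    k, K_f, n_c, N = int(overlap), int(set_size), int(draw_size), int(universe)
    if not (0 <= k <= min(K_f, n_c) and K_f <= N and n_c <= N):
        raise ParameterError(
            f"inconsistent counts: k={k}, set={K_f}, draw={n_c}, universe={N}"
        )
    return float(hypergeom.sf(k - 1, N, K_f, n_c))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_bubble_table(selection: SelectionReport,
                       clustering: ClusteringResult,
                       annot: AnnotationMap,
                       variable_ids=None,
                       universe: str = "selected") -> pd.DataFrame:
    """Assemble the (cluster x function) over-representation table.

    Parameters
    ----------
    selection : which variables survived the PIP filter
    clustering : cluster labels aligned with `variable_ids`
    annot : the annotation map
    variable_ids : ids aligned with clustering.labels (defaults to the ids
        stored on the selection's source, required to map labels to ids)
    universe : "selected" (proteins hosting >= 1 selected variable, default)
        or "annotation" (every protein in the map)

    Returns
    -------
    DataFrame with columns cluster, function, event_count, protein_count,
    p, q, significant — one row per (cluster, function) with >= 1 event.
    """
    if universe not in ("selected", "annotation"):
        raise ParameterError(f"unknown universe policy: {universe!r}")
    if variable_ids is None:
        raise ParameterError("variable_ids aligned with the clustering are "
                             "required")
    label_of = dict(zip(variable_ids, clustering.labels))
    selected = [v for v in selection.retained_ids if v in label_of]

    annotated = [v for v in selected if v in annot.variable_to_protein]
    if not annotated:
        import warnings
        warnings.warn("no selected variable is annotated; empty table",
                      RuntimeWarning)
        return pd.DataFrame(columns=["cluster", "function", "event_count",
                                     "protein_count", "p", "q", "significant"])

    if universe == "selected":
        universe_proteins = {annot.variable_to_protein[v] for v in annotated}
    else:
        universe_proteins = set(annot.protein_to_functions) | set(
            annot.variable_to_protein.values()
        )
    N = len(universe_proteins)
    proteins_with = {
        fn: {pr for pr in universe_proteins
             if fn in annot.protein_to_functions.get(pr, set())}
        for fn in annot.all_functions
    }

    rows = []
    for cluster in sorted(set(label_of[v] for v in annotated)):
        members = [v for v in annotated if label_of[v] == cluster]
        cluster_proteins = {annot.variable_to_protein[v] for v in members}
        n_c = len(cluster_proteins)
        for fn in sorted(annot.all_functions):
            events = [v for v in members
                      if fn in annot.functions_of_variable(v)]
            if not events:
                continue
            hit_proteins = {annot.variable_to_protein[v] for v in events}
            k = len(hit_proteins)
            K_f = len(proteins_with[fn])
            p = hypergeometric_test(k, K_f, n_c, N)
            rows.append({"cluster": int(cluster), "function": fn,
                         "event_count": len(events), "protein_count": k,
                         "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < SIGNIFICANCE_Q
    return table
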