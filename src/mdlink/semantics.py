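"""Disease semantic similarity from MeSH-style tree numbers.

A disease's position in the MeSH hierarchy is given by dot-separated tree
numbers (e.g. ``C04.588.180``).  Ancestors are obtained by repeatedly
dropping the last component, yielding a directed acyclic graph of the
disease and its ancestor terms.  Each term T contributes semantically with
weight 1 for the disease itself and, for ancestors, ``theta`` times the best
contribution among its children in the DAG (default decay theta = 0.5).
Two diseases are similar in proportion to the summed contributions of the
terms their DAGs share, normalised by their total semantic values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DECAY = 0.5


class TreeNumberError(ValueError):
    """Raised for empty or malformed MeSH tree numbers."""


def _prefixes(tree_number: str) -> list[str]:
    """All dot-prefixes of a tree number, shortest first."""
    if not tree_number or tree_number.startswith(".") or tree_number.endswith("."):
        raise TreeNumberError(f"malformed tree number {tree_number!r}")
    parts = tree_number.split(".")
    if any(not p for p in parts):
        raise TreeNumberError(f"malformed tree number {tree_number!r}")
    return [".".join(parts[: i + 1]) for i in range(len(parts))]


@dataclass(frozen=True)
class DiseaseDag:
    """The DAG of one disease: its tree-number terms plus all ancestors.

    ``terms`` holds every prefix of every tree number; ``self_terms`` are the
    full tree numbers (the disease's own positions, contribution 1);
    ``edges`` are (parent, child) pairs within ``terms``.
    """

    disease_id: str
    terms: frozenset[str]
    self_terms: frozenset[str]
    edges: frozenset[tuple[str, str]]


def dag_from_tree_numbers(
    table: Mapping[str, Sequence[str]]
) -> dict[str, DiseaseDag]:
    """Build per-disease DAGs from a disease -> tree-numbers mapping."""
    dags: dict[str, DiseaseDag] = {}
    for disease in sorted(table):
        numbers = list(table[disease])
        if not numbers:
            raise TreeNumberError(f"disease {disease!r} has no tree numbers")
        terms: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for num in numbers:
            chain = _prefixes(num)
            terms.update(chain)
            edges.update(zip(chain[:-1], chain[1:]))
        dags[disease] = DiseaseDag(
            disease_id=disease,
            terms=frozenset(terms),
            self_terms=frozenset(numbers),
            edges=frozenset(edges),
        )
    return dags


def load_mesh_table(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV ``disease_id<TAB>tree_number`` (one row each)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["disease_id", "tree_number"], dtype=str,
    )
    table: dict[str, list[str]] = {}
    for did, num in zip(df.disease_id, df.tree_number):
        table.setdefault(did, []).append(num)
    return table


def contribution(dag: DiseaseDag, theta: float = DEFAULT_DECAY) -> dict[str, float]:
    """Semantic contribution D_d(T) of every term in the DAG.

    The disease's own terms contribute 1; every other term contributes
    ``theta`` times the maximum contribution among its children, i.e.
    ``theta ** k`` along the shortest hop count to a self term.  Terms are
    processed deepest-first so each child is resolved before its parents.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"decay must be in (0, 1], got {theta}")
    children: dict[str, list[str]] = {}
    for parent, child in dag.edges:
        children.setdefault(parent, []).append(child)
    contrib: dict[str, float] = {}
    for term in sorted(dag.terms, key=lambda t: -t.count(".")):
        if term in dag.self_terms:
            contrib[term] = 1.0
        else:
            kids = [c for c in children.get(term, ()) if c in contrib]
            if not kids:
                raise TreeNumberError(
                    f"term {term!r} in DAG of {dag.disease_id!r} has no "
                    "resolvable child"
                )
            contrib[term] = theta * max(contrib[c] for c in kids)
    return contrib


def semantic_value(cmap: Mapping[str, float]) -> float:
    """Total semantic value DV = sum of term contributions (>= 1)."""
    if not cmap:
        raise ValueError("empty contribution map")
    return float(sum(cmap.values()))


def semantic_similarity(
    a: str,
    b: str,
    dags: Mapping[str, DiseaseDag],
    theta: float = DEFAULT_DECAY,
) -> float:
    """Shared-ancestor similarity of two diseases, in [0, 1].

    S(a, b) = sum over shared terms of (D_a(T) + D_b(T)) divided by
    (DV(a) + DV(b)); 1 for identical DAGs, 0 for disjoint ones.
    """
    for d in (a, b):
        if d not in dags:
            raise KeyError(f"unknown disease id {d!r}")
    ca = contribution(dags[a], theta)
    cb = contribution(dags[b], theta)
    shared = set(ca) & set(cb)
    num = sum(ca[t] + cb[t] for t in shared)
    s = num / (semantic_value(ca) + semantic_value(cb))
    return float(np.clip(s, 0.0, 1.0))


def disease_similarity_matrix(
    dags: Mapping[str, DiseaseDag], theta: float = DEFAULT_DECAY
) -> pd.DataFrame:
    """Pairwise semantic similarity over all diseases, sorted id order."""
    ids = sorted(dags)
    if len(ids) < 2:
        raise ValueError("need at least two diseases")
    contribs = {d: contribution(dags[d], theta) for d in ids}
    dvs = {d: semantic_value(contribs[d]) for d in ids}
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        ci = contribs[ids[i]]
        for j in range(i + 1, n):
            cj = contribs[ids[j]]
            shared = set(ci) & set(cj)
            s = sum(ci[t] + cj[t] for t in shared) / (dvs[ids[i]] + dvs[ids[j]])
            sim[i, j] = sim[j, i] = min(max(s, 0.0), 1.0)
    return pd.DataFrame(sim, index=ids, columns=ids)


def dags_with_fallback(
    table: Mapping[str, Sequence[str]], all_disease_ids: Sequence[str]
) -> dict[str, DiseaseDag]:
    """DAGs for every id in ``all_disease_ids``; ids missing from the table
    get a self-only DAG (similar only to themselves) with a logged warning."""
    dags = dag_from_tree_numbers(table)
    for did in all_disease_ids:
        if did not in dags:
            logger.warning("disease %s has no tree numbers; self-only DAG", did)
            term = f"UNMAPPED.{did}"
            dags[did] = DiseaseDag(
                disease_id=did,
                terms=frozenset({term}),
                self_terms=frozenset({term}),
                edges=frozenset(),
            )
    return dags
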