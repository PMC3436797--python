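"""Gold-standard handling and cluster-vs-module agreement metrics.

Predicted clusters are validated against a reference collection of
functional modules — typically the protein sets annotated to Gene Ontology
terms.  Two filters make the reference informative:

* **Information content.**  ``IC(g) = -log(|g| / |root|)`` where ``root``
  is the term's ontology category (biological process, molecular function
  or cellular component).  General terms annotating a large fraction of the
  corpus have low IC; keeping only terms with IC above a cutoff (default 2)
  restricts evaluation to specific modules of the kind clustering can find.
* **Minimum size.**  Terms annotating fewer than 3 proteins are removed.

A cluster *matches* a module when their neighborhood affinity reaches a
threshold ``theta`` (conventionally 0.25).  Precision is the fraction of
clusters matching some module, recall the fraction of modules matched by
some cluster, and the F-measure their harmonic mean.  Coverage counts the
distinct nodes assigned to any cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .postprocess import neighborhood_affinity

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "EvalResult",
    "information_content",
    "load_gold_standard",
    "evaluate",
]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


def information_content(
    term_size: int, root_size: int, log_base: str | float = "e"
) -> float:
    """``-log(term_size / root_size)``; 0 iff the term covers its whole root."""
    if not 1 <= term_size <= root_size:
        raise ValueError(
            f"term_size must lie in [1, root_size]; got {term_size} vs root {root_size}"
        )
    base = _LOG_BASES.get(str(log_base), None)
    if base is None:
        base = float(log_base)
    return -math.log(term_size / root_size, base)


@dataclass
class GoldStandard:
    """Reference modules: term id -> protein set, after IC/size filtering."""

    terms: dict[str, frozenset]
    ic: dict[str, float] = field(default_factory=dict)
    ic_min: float | None = None
    min_size: int = 3

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @classmethod
    def from_modules(cls, modules: Mapping[str, Iterable[Hashable]]) -> "GoldStandard":
        """Wrap already-curated modules (e.g. planted truth) without filtering."""
        return cls(terms={t: frozenset(m) for t, m in modules.items()})


def load_gold_standard(
    path,
    root_sizes: int | Mapping[str, int],
    ic_min: float | None = 2.0,
    min_size: int = 3,
    restrict_to: Iterable[Hashable] | None = None,
    term_category: Mapping[str, str] | None = None,
    log_base: str | float = "e",
) -> GoldStandard:
    """Read a two-column ``term_id<TAB>protein_id`` file and filter it.

    IC is computed from the *unrestricted* term size (term specificity is a
    property of the annotation corpus, not of one network) against the root
    size of the term's category; the size filter applies *after* restricting
    each term to ``restrict_to`` (the network's nodes), because a term
    barely present in the network cannot be recovered from it.

    ``root_sizes`` is either a single root size (one category) or a mapping
    category -> size, in which case ``term_category`` must map every term to
    a known category.
    """
    annotations: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'term_id protein_id', got {line!r}"
                )
            annotations.setdefault(tokens[0], set()).add(tokens[1])

    restrict = set(restrict_to) if restrict_to is not None else None
    terms: dict[str, frozenset] = {}
    ic_values: dict[str, float] = {}
    for term, proteins in annotations.items():
        if ic_min is not None:
            if isinstance(root_sizes, Mapping):
                if term_category is None or term not in term_category:
                    raise ValueError(f"no category known for term {term!r}")
                category = term_category[term]
                if category not in root_sizes:
                    raise ValueError(
                        f"unknown category {category!r} for term {term!r}"
                    )
                root = root_sizes[category]
            else:
                root = int(root_sizes)
            ic = information_content(len(proteins), root, log_base)
            if not ic > ic_min:
                continue
        else:
            ic = float("nan")
        kept = proteins if restrict is None else proteins & restrict
        if len(kept) < min_size:
            continue
        terms[term] = frozenset(kept)
        if ic_min is not None:
            ic_values[term] = ic
    return GoldStandard(terms=terms, ic=ic_values, ic_min=ic_min, min_size=min_size)


@dataclass
class EvalResult:
    """Neighborhood-affinity agreement between clusters and reference modules."""

    precision: float
    recall: float
    f_measure: float
    coverage: int
    n_clusters: int
    n_terms: int
    matched_clusters: int
    matched_terms: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "coverage": self.coverage,
            "n_clusters": self.n_clusters,
            "n_terms": self.n_terms,
            "matched_clusters": self.matched_clusters,
            "matched_terms": self.matched_terms,
        }


def evaluate(
    clusters: Sequence[Iterable[Hashable]],
    gold: GoldStandard,
    theta: float = 0.25,
) -> EvalResult:
    """NA-threshold precision, recall, F-measure and coverage.

    A cluster counts toward precision if some reference module has
    ``NA >= theta`` with it; a module counts toward recall if some cluster
    reaches it.  ``theta = 1`` accepts only exact set equality.
    """
    if not 0 < theta <= 1:
        raise ValueError(f"theta must lie in (0, 1], got {theta}")
    cluster_sets = [frozenset(c) for c in clusters]
    if not cluster_sets:
        logger.warning("evaluate: empty cluster list; all metrics are 0")
        return EvalResult(0.0, 0.0, 0.0, 0, 0, gold.n_terms, 0, 0)
    matched_clusters = 0
    matched_terms: set[str] = set()
    for c in cluster_sets:
        hit = False
        for term, g in gold.terms.items():
            if neighborhood_affinity(c, g) >= theta:
                matched_terms.add(term)
                hit = True
        if hit:
            matched_clusters += 1
    precision = matched_clusters / len(cluster_sets)
    recall = len(matched_terms) / gold.n_terms if gold.n_terms else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    coverage = len(set().union(*cluster_sets))
    return EvalResult(
        precision=precision,
        recall=recall,
        f_measure=f,
        coverage=coverage,
        n_clusters=len(cluster_sets),
        n_terms=gold.n_terms,
        matched_clusters=matched_clusters,
        matched_terms=len(matched_terms),
    )
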