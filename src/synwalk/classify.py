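"""Merging-pattern subtype classification of 3-synergy solutions.

In hemiparetic gait, two of the four canonical motor modules can merge
into a single extracted synergy, reducing the synergy count from four
to three.  The merged pair defines a walking-impairment subtype:
modules 1+2 (stance; subtype 1), modules 1+4 (swing-to-stance
transition; subtype 2), or modules 3+4 (swing; subtype 3).

A muscle contributes significantly to a synergy when its unit-norm
weight coefficient is at least 0.3 (assessed in the comfortable-walking
condition).  A synergy is assigned a module when its significant-muscle
set covers that module's distinctive muscles (members of no other
module — the biarticular rectus femoris, shared between modules 1 and
3, is never decisive alone).  A synergy carrying two modules is a
merged synergy; ambiguous coverage falls back to cosine similarity
against graded module templates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .templates import ModuleTemplateSet, SUBTYPE_OF_PAIR, make_canonical_modules

__all__ = [
    "SubtypeLabel",
    "significant_muscles",
    "assign_modules",
    "classify",
]


@dataclass
class SubtypeLabel:
    """Classification outcome with per-synergy evidence.

    ``label`` is one of ``subtype1`` / ``subtype2`` / ``subtype3``
    (merged pairs {1,2} / {1,4} / {3,4}), ``other_merge`` (a merged pair
    outside those three), ``non_merged``, or ``unclassified`` (wrong
    synergy count or irresolvably ambiguous weights).
    """

    label: str
    merged_modules: tuple[int, int] | None = None
    evidence: dict = field(default_factory=dict)


def significant_muscles(
    w_col: np.ndarray,
    muscle_order: tuple[str, ...],
    threshold: float = 0.3,
) -> frozenset[str]:
    """Muscles whose unit-norm weight coefficient is at least ``threshold``.

    The column is re-normalized to unit Euclidean norm first, so the
    0.3 threshold is well defined regardless of the scale the
    factorization returned.
    """
    w = np.asarray(w_col, dtype=float)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    sig = frozenset(m for m, wi in zip(muscle_order, w) if wi >= threshold)
    if not sig:
        warnings.warn("no muscle reaches the significance threshold in this synergy",
                      stacklevel=2)
    return sig


def assign_modules(
    significant: frozenset[str] | set[str],
    templates: ModuleTemplateSet,
    cover_frac: float = 1.0,
) -> frozenset[int]:
    """Module ids whose distinctive muscles the significant set covers.

    A module is assigned when at least ``cover_frac`` of its distinctive
    muscles (members of that module only) are significant in the
    synergy.  A synergy may carry zero, one, or several module ids; two
    or more ids mark a merged synergy.
    """
    assigned = set()
    for mod, distinct in templates.distinctive.items():
        if not distinct:
            continue
        covered = len(distinct & set(significant))
        if covered >= cover_frac * len(distinct):
            assigned.add(mod)
    return frozenset(assigned)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _cosine_assignment(
    W: np.ndarray, templates: ModuleTemplateSet
) -> list[tuple[frozenset[int], float]]:
    """Best-matching module set (single id or pair) per synergy column,
    by cosine similarity against graded templates."""
    candidates: list[tuple[frozenset[int], np.ndarray]] = []
    for mod in (1, 2, 3, 4):
        candidates.append((frozenset({mod}), templates.module_column(mod)))
    for pair in itertools.combinations((1, 2, 3, 4), 2):
        candidates.append((frozenset(pair), templates.merged_column(pair)))
    out = []
    for j in range(W.shape[1]):
        scored = [(mods, _cosine(W[:, j], tpl)) for mods, tpl in candidates]
        mods, cos = max(scored, key=lambda x: x[1])
        out.append((mods, cos))
    return out


def _pattern_label(assignments: list[frozenset[int]]) -> SubtypeLabel | None:
    """Subtype from per-synergy module sets, or None when ambiguous."""
    merged = [a for a in assignments if len(a) >= 2]
    singles = [a for a in assignments if len(a) == 1]
    if not merged:
        return SubtypeLabel(label="non_merged")
    if (
        len(merged) == 1
        and len(merged[0]) == 2
        and len(singles) == 2
        and len(frozenset().union(*assignments)) == 4
    ):
        pair = tuple(sorted(merged[0]))
        label = SUBTYPE_OF_PAIR.get(pair, "other_merge")
        return SubtypeLabel(label=label, merged_modules=pair)
    return None


def classify(
    W: np.ndarray,
    templates: ModuleTemplateSet | None = None,
    muscle_order: tuple[str, ...] | None = None,
    threshold: float = 0.3,
    cover_frac: float = 1.0,
) -> SubtypeLabel:
    """Classify a 3-synergy weight matrix into a merging subtype.

    ``W`` is muscles x n with rows in ``templates.muscle_order`` (or
    ``muscle_order``).  Solutions with n != 3 are labelled
    ``unclassified`` — the merging analysis is defined only for
    three-synergy participants.  The threshold pattern decides the
    label; when the pattern is ambiguous the cosine fallback against
    graded templates is tried, and only if that is also inconsistent is
    the result ``unclassified`` (with full evidence attached).
    """
    W = np.asarray(W, dtype=float)
    if templates is None:
        templates = make_canonical_modules(muscle_order or ())
    if W.shape[0] != len(templates.muscle_order):
        raise ValueError("W row count must match the template muscle order")

    if W.shape[1] != 3:
        return SubtypeLabel(
            label="unclassified",
            evidence={"reason": f"classification requires 3 synergies, got {W.shape[1]}"},
        )

    sig_sets = [
        significant_muscles(W[:, j], templates.muscle_order, threshold)
        for j in range(3)
    ]
    assignments = [assign_modules(s, templates, cover_frac) for s in sig_sets]
    evidence: dict = {
        "significant_muscles": [sorted(s) for s in sig_sets],
        "module_assignments": [sorted(a) for a in assignments],
    }

    result = _pattern_label(assignments)
    if result is None:
        cos_assign = _cosine_assignment(W, templates)
        evidence["cosine_assignments"] = [
            (sorted(mods), round(c, 4)) for mods, c in cos_assign
        ]
        result = _pattern_label([mods for mods, _ in cos_assign])
        if result is not None:
            evidence["resolved_by"] = "cosine_templates"
    if result is None:
        result = SubtypeLabel(label="unclassified",
                              evidence={"reason": "ambiguous module coverage"})
    result.evidence = {**evidence, **result.evidence}
    return result
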