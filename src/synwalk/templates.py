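"""Canonical motor modules of human walking.

Healthy comfortable walking is well described by four muscle synergies
("motor modules"): hip/knee extensors (module 1), ankle plantar flexors
(module 2), hip flexors and ankle dorsiflexors (module 3), and knee
flexors (module 4).  This module encodes the membership of the eight
paretic-side muscles recorded in a standard hemiparetic-gait protocol
(TA, Sol, MG, VM, RF, MH, LH, GM) in those four modules, together with
graded template weight vectors used both by the synthetic generator and
as a cosine-similarity fallback by the subtype classifier.

The rectus femoris is biarticular (hip flexor / knee extensor) and is a
member of both modules 1 and 3; it is therefore never *distinctive* of
either module and must not decide a module assignment on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MUSCLES",
    "ModuleTemplateSet",
    "make_canonical_modules",
    "SUBTYPE_OF_PAIR",
    "PAIR_OF_SUBTYPE",
]

#: Canonical short labels in recording order.
MUSCLES: tuple[str, ...] = ("TA", "Sol", "MG", "VM", "RF", "MH", "LH", "GM")

# Accepted aliases (case-insensitive) for each canonical label.
_ALIASES: dict[str, str] = {
    "ta": "TA", "tibialis anterior": "TA", "tibialis_anterior": "TA",
    "sol": "Sol", "soleus": "Sol",
    "mg": "MG", "medial gastrocnemius": "MG", "medial_gastrocnemius": "MG",
    "vm": "VM", "vastus medialis": "VM", "vastus_medialis": "VM",
    "rf": "RF", "rectus femoris": "RF", "rectus_femoris": "RF",
    "mh": "MH", "semitendinosus": "MH", "medial hamstring": "MH",
    "lh": "LH", "biceps femoris": "LH", "lateral hamstring": "LH",
    "gm": "GM", "gluteus medius": "GM", "gluteus_medius": "GM",
}

#: Module membership: module id -> muscle labels.
MODULE_MEMBERSHIP: dict[int, frozenset[str]] = {
    1: frozenset({"VM", "RF", "GM"}),   # hip/knee extensors
    2: frozenset({"Sol", "MG"}),        # ankle plantar flexors
    3: frozenset({"TA", "RF"}),         # hip flexors + ankle dorsiflexors
    4: frozenset({"MH", "LH"}),         # knee flexors
}

# Graded (pre-normalization) weights of each module's member muscles.
# RF carries a smaller weight in module 3 than its primary role in
# module 1, reflecting its mixed contribution.
_GRADED_WEIGHTS: dict[int, dict[str, float]] = {
    1: {"VM": 0.80, "RF": 0.60, "GM": 0.70},
    2: {"Sol": 0.75, "MG": 0.75},
    3: {"TA": 0.90, "RF": 0.50},
    4: {"MH": 0.75, "LH": 0.75},
}

#: Merged module pair -> walking-impairment subtype label.
SUBTYPE_OF_PAIR: dict[tuple[int, int], str] = {
    (1, 2): "subtype1",
    (1, 4): "subtype2",
    (3, 4): "subtype3",
}
PAIR_OF_SUBTYPE: dict[str, tuple[int, int]] = {v: k for k, v in SUBTYPE_OF_PAIR.items()}


def canonical_label(name: str) -> str:
    """Map a muscle name or alias to its canonical short label."""
    key = name.strip()
    if key in MUSCLES:
        return key
    try:
        return _ALIASES[key.lower()]
    except KeyError:
        raise ValueError(f"unknown muscle label: {name!r}") from None


@dataclass(frozen=True)
class ModuleTemplateSet:
    """Membership of the eight recorded muscles in modules 1-4.

    Attributes
    ----------
    muscle_order
        Canonical labels in the caller-supplied order; template vectors
        are aligned to this order.
    membership
        module id -> set of member muscle labels.
    distinctive
        module id -> labels belonging to that module only (shared
        biarticular muscles excluded); used for module assignment.
    weights
        8 x 4 array of graded template weights, unit Euclidean norm per
        column, rows aligned to ``muscle_order``, columns to modules 1-4.
    """

    muscle_order: tuple[str, ...]
    membership: dict[int, frozenset[str]] = field(default_factory=lambda: dict(MODULE_MEMBERSHIP))
    weights: np.ndarray | None = None

    @property
    def distinctive(self) -> dict[int, frozenset[str]]:
        counts: dict[str, int] = {}
        for members in self.membership.values():
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        return {
            mod: frozenset(m for m in members if counts[m] == 1)
            for mod, members in self.membership.items()
        }

    def module_column(self, module_id: int) -> np.ndarray:
        """Unit-norm template weight vector of one module."""
        return self.weights[:, module_id - 1]

    def merged_column(self, pair: tuple[int, int]) -> np.ndarray:
        """Unit-norm weight vector of two merged modules (normalized sum)."""
        a, b = pair
        col = self.module_column(a) + self.module_column(b)
        return col / np.linalg.norm(col)


def make_canonical_modules(muscle_names: list[str] | tuple[str, ...]) -> ModuleTemplateSet:
    """Build the canonical module templates for the 8 recorded muscles.

    Parameters
    ----------
    muscle_names
        Exactly the eight recorded muscle labels (canonical short labels
        or common aliases), in any order.

    Returns
    -------
    ModuleTemplateSet
        Membership map and graded template vectors aligned to the given
        muscle order.

    Raises
    ------
    ValueError
        If the list does not contain exactly the eight recorded muscles
        (unknown labels, duplicates, or wrong count).
    """
    labels = tuple(canonical_label(m) for m in muscle_names)
    if len(labels) != 8:
        raise ValueError(f"expected exactly 8 muscle labels, got {len(labels)}")
    if len(set(labels)) != 8:
        dupes = sorted({m for m in labels if labels.count(m) > 1})
        raise ValueError(f"duplicate muscle labels: {dupes}")

    W = np.zeros((8, 4))
    for mod, graded in _GRADED_WEIGHTS.items():
        for muscle, w in graded.items():
            W[labels.index(muscle), mod - 1] = w
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    return ModuleTemplateSet(muscle_order=labels, weights=W)
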