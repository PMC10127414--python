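"""Node-set and region-of-interest naming.

The covariance network is built over 17 nodes: the 5 cholinergic
basal-forebrain subfields and the 12 subfields of the right hippocampus.
Canonical column names keep the anatomical labels verbatim (including
``Ch4a-i``, ``Ch1/2``, ``CA2/3``); :func:`sanitize_label` provides a
filesystem-safe alias used for output file names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASAL_FOREBRAIN_SUBFIELDS: tuple[str, ...] = ("Ch4p", "Ch4a-i", "Ch3", "NSP", "Ch1/2")

RIGHT_HIPPOCAMPAL_SUBFIELDS: tuple[str, ...] = (
    "Tail",
    "Subiculum",
    "CA1",
    "Fissure",
    "Presubiculum",
    "Parasubiculum",
    "Molecular layer",
    "Dentate gyrus",
    "CA2/3",
    "CA4",
    "Fimbria",
    "HATA",
)

#: The 15 whole-structure subcortical volumes compared across groups.
SUBCORTICAL_NUCLEI: tuple[str, ...] = (
    "Basal forebrain",
    "L-Thalamus",
    "L-Caudate",
    "L-Putamen",
    "L-Pallidum",
    "L-Hippocampus",
    "L-Amygdala",
    "L-Accumbens",
    "R-Thalamus",
    "R-Caudate",
    "R-Putamen",
    "R-Pallidum",
    "R-Hippocampus",
    "R-Amygdala",
    "R-Accumbens",
)

ALL_ROIS: tuple[str, ...] = (
    SUBCORTICAL_NUCLEI + BASAL_FOREBRAIN_SUBFIELDS + RIGHT_HIPPOCAMPAL_SUBFIELDS
)

GROUPS: tuple[str, ...] = ("NC", "G-SCD", "B-SCD", "MCI")


def sanitize_label(label: str) -> str:
    """Filesystem-safe alias for an anatomical label (``Ch1/2`` -> ``Ch1_2``)."""
    out = label
    for ch in "/ -":
        out = out.replace(ch, "_")
    return out


@dataclass(frozen=True)
class NodeSet:
    """Ordered, unique node names of the covariance network.

    The default is the 17-node set of basal-forebrain plus right
    hippocampal subfields; node order fixes matrix row/column order and
    the lexicographic edge tie rule everywhere downstream.
    """

    names: tuple[str, ...] = field(
        default=BASAL_FOREBRAIN_SUBFIELDS + RIGHT_HIPPOCAMPAL_SUBFIELDS
    )

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate node names: {dupes}")
        if len(self.names) < 2:
            raise ValueError("a node set needs at least 2 nodes")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def n_pairs(self) -> int:
        n = len(self.names)
        return n * (n - 1) // 2

    def sanitized(self) -> tuple[str, ...]:
        return tuple(sanitize_label(n) for n in self.names)


DEFAULT_NODE_SET = NodeSet()
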