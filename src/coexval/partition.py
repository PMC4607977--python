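"""Module partitions: gene -> module label maps with a reserved gray label.

Genes left unassigned by module detection carry the reserved gray label
("grey", following the WGCNA colour convention); detected modules are
named by the standard colour sequence in order of decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GRAY_LABEL = "grey"

# Standard WGCNA colour order used to label modules by descending size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


def color_name(rank: int) -> str:
    """Colour label for the module of the given size rank (0 = largest)."""
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


@dataclass
class ModulePartition:
    """Mapping of gene ids to module labels.

    Attributes
    ----------
    labels : Series
        Index = gene ids, values = module label strings (gray included).
    gray_label : str
        Reserved label for unassigned genes.
    min_size : int
        Minimum module size in force when the partition was produced.
    """

    labels: pd.Series
    gray_label: str = GRAY_LABEL
    min_size: int = 3

    def __post_init__(self):
        self.labels = pd.Series(self.labels).astype(str)

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def module_names(self) -> list[str]:
        """Non-gray module labels, ordered by descending size (stable)."""
        counts = self.labels[self.labels != self.gray_label].value_counts()
        return sorted(counts.index, key=lambda m: (-counts[m], m))

    @property
    def n_modules(self) -> int:
        return len(self.module_names)

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def gray_genes(self) -> pd.Index:
        return self.members(self.gray_label)

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != self.gray_label].value_counts()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.labels.index, "module": self.labels.values})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gray_label: str = GRAY_LABEL, min_size: int = 3):
        labels = pd.Series(frame.iloc[:, 1].values, index=frame.iloc[:, 0].values, name="module")
        return cls(labels=labels, gray_label=gray_label, min_size=min_size)
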