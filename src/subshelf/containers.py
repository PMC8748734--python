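"""Shared in-memory containers.

Tables move through the package as pandas DataFrames with documented
schemas; :class:`AbundanceMatrix` wraps a features × samples matrix with
an explicit value-kind tag so that transforms cannot silently mix scales
(raw counts vs RPKM vs copies-per-organism vs TPM/CPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError

#: Recognized value kinds for abundance matrices.
VALUE_KINDS = (
    "counts",
    "RPKM",
    "copies_per_organism",
    "TPM",
    "CPM",
    "relative",
)


@dataclass
class AbundanceMatrix:
    """A features × samples numeric matrix with an explicit value-kind tag.

    Attributes
    ----------
    data:
        Features (genes, families, pathways, genomes, taxa) as the index,
        samples as columns.
    value_kind:
        One of :data:`VALUE_KINDS`; propagated through transforms.
    total_reads:
        Optional per-sample library sizes (the RPKM denominator), indexed
        by sample.
    """

    data: pd.DataFrame
    value_kind: str
    total_reads: pd.Series | None = field(default=None)

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ConfigError(
                f"value_kind {self.value_kind!r} not one of {VALUE_KINDS}"
            )
        if (self.data.to_numpy() < 0).any():
            raise ConfigError("abundance values must be non-negative")
        if self.total_reads is not None:
            self.total_reads = pd.Series(self.total_reads)
            missing = [c for c in self.data.columns if c not in self.total_reads.index]
            if missing:
                raise ConfigError(f"total_reads missing for samples: {missing}")

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def features(self) -> list:
        return list(self.data.index)

    def with_data(self, data: pd.DataFrame, value_kind: str | None = None) -> "AbundanceMatrix":
        """Return a copy carrying ``data`` (and optionally a new kind)."""
        return AbundanceMatrix(
            data=data,
            value_kind=self.value_kind if value_kind is None else value_kind,
            total_reads=self.total_reads,
        )
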