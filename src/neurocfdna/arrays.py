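"""Container and I/O for methylation-array beta matrices.

A :class:`BetaMatrix` holds SWAN-normalised (or otherwise pre-normalised)
beta values — fraction methylation in [0, 1] — for a set of array probes
across samples, together with probe coordinates and a neuron/plasma group
label per sample. Normalisation itself is out of scope: this package
consumes already-normalised betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BetaMatrix", "GROUP_NEURON", "GROUP_PLASMA"]

GROUP_NEURON = "neuron"
GROUP_PLASMA = "plasma"
META_COLUMNS = ("probe_id", "chrom", "pos")


@dataclass
class BetaMatrix:
    """Probes x samples beta values with coordinates and group labels.

    Attributes
    ----------
    betas
        DataFrame indexed by probe_id, one float column per sample.
    probes
        DataFrame indexed by probe_id with columns ``chrom`` and ``pos``
        (1-based), sorted by position within each chromosome.
    groups
        Series mapping sample id -> ``"neuron"`` or ``"plasma"``.
    """

    betas: pd.DataFrame
    probes: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.probes.index):
            raise ValueError("betas and probes must share a probe_id index")
        vals = self.betas.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.betas.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.unique()) - {GROUP_NEURON, GROUP_PLASMA}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for _, sub in self.probes.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("probe positions must be sorted within chromosome")

    @property
    def n_probes(self) -> int:
        return len(self.betas)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.betas.columns if self.groups[s] == group]

    def subset_samples(self, keep: list[str]) -> "BetaMatrix":
        return BetaMatrix(self.betas[keep], self.probes, self.groups[keep])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, betas_path, groups_path) -> None:
        """Write the matrix (probe_id/chrom/pos + one column per sample) and
        a sidecar sample->group table, both TSV."""
        out = self.probes.reset_index()
        out.columns = list(META_COLUMNS)
        out = pd.concat([out, self.betas.reset_index(drop=True)], axis=1)
        out.to_csv(betas_path, sep="\t", index=False, float_format="%.6g")
        self.groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
            groups_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, betas_path, groups_path) -> "BetaMatrix":
        raw = pd.read_csv(betas_path, sep="\t")
        for col in META_COLUMNS:
            if col not in raw.columns:
                raise ValueError(f"beta matrix file lacks required column {col!r}")
        probes = raw[list(META_COLUMNS)].set_index("probe_id")
        betas = raw.drop(columns=["chrom", "pos"]).set_index("probe_id").astype(float)
        gtab = pd.read_csv(groups_path, sep="\t")
        groups = gtab.set_index("sample_id")["group"]
        return cls(betas, probes, groups)
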