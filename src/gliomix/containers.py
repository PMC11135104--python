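"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class MultiOmicsDataset:
    """A sample-aligned collection of omics blocks with labels and survival.

    Attributes
    ----------
    blocks
        Mapping block name -> DataFrame of shape (n samples, p features),
        indexed by sample ID. All blocks share the same index, in the same
        order.
    labels
        Class label per sample (pd.Series indexed like the blocks).
    survival
        Optional DataFrame with columns ``time`` (positive float) and
        ``event`` (0 = censored, 1 = event), indexed like the blocks.
    truth
        For simulated data: block name -> list of informative feature names.
        Empty for real data.
    """

    blocks: dict[str, pd.DataFrame]
    labels: pd.Series
    survival: pd.DataFrame | None = None
    truth: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.labels.index
        for name, X in self.blocks.items():
            if not X.index.equals(idx):
                raise ValueError(f"block {name!r} is not sample-aligned with labels")
            if X.isna().any().any():
                raise ValueError(f"block {name!r} contains missing values")
        if self.survival is not None and not self.survival.index.equals(idx):
            raise ValueError("survival table is not sample-aligned with labels")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        # first-appearance order, the convention used throughout
        return list(dict.fromkeys(self.labels))

    def subset(self, sample_ids) -> "MultiOmicsDataset":
        """Restrict every table to ``sample_ids`` (kept in the given order)."""
        ids = list(sample_ids)
        return MultiOmicsDataset(
            blocks={k: v.loc[ids] for k, v in self.blocks.items()},
            labels=self.labels.loc[ids],
            survival=None if self.survival is None else self.survival.loc[ids],
            truth=dict(self.truth),
        )

    def write(self, outdir: str | Path) -> None:
        """Write one TSV per block (features x samples), samples.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, X in self.blocks.items():
            X.T.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="feature")
        samples = pd.DataFrame({"sample_id": self.labels.index, "class": self.labels.values})
        if self.survival is not None:
            samples["time"] = self.survival["time"].values
            samples["event"] = self.survival["event"].values
        samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def read_block(path: str | Path, features_in_rows: bool = True) -> pd.DataFrame:
    """Read a block TSV/CSV into a (samples x features) DataFrame.

    ``features_in_rows=True`` matches the on-disk layout written by
    :meth:`MultiOmicsDataset.write` (features x samples, header = sample IDs).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.T if features_in_rows else df


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample table (sample_id, class[, time, event]) indexed by sample_id."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return df.set_index("sample_id")


def read_blacklist(path: str | Path) -> set[str]:
    """One feature name per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_dataset(directory: str | Path, block_names: list[str] | None = None) -> MultiOmicsDataset:
    """Load a dataset previously written with :meth:`MultiOmicsDataset.write`."""
    directory = Path(directory)
    samples = read_samples(directory / "samples.tsv")
    if block_names is None:
        block_names = sorted(
            p.stem for p in directory.glob("*.tsv") if p.name != "samples.tsv"
        )
    blocks = {name: read_block(directory / f"{name}.tsv").loc[samples.index] for name in block_names}
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    survival = None
    if {"time", "event"}.issubset(samples.columns):
        survival = samples[["time", "event"]]
    labels = samples["class"]
    labels.name = "class"
    return MultiOmicsDataset(blocks=blocks, labels=labels, survival=survival, truth=truth)
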