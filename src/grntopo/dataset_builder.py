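"""Instance tables, train/test splits, balanced training sets and null controls.

An *instance* is a (gene, role) pair: a dual-role gene contributes one
``regulator`` row and one ``target`` row, mirroring how regulators repeated as
targets are kept in real GRN datasets.  The held-out test set takes 10% of the
regulators plus the same number of targets, so it is exactly class-balanced.
Because targets vastly outnumber regulators, training data is undersampled
into several balanced sets: the targets are shuffled and chunked into groups
the size of the regulator pool, and every chunk is joined with all regulators.
Label-shuffled copies of the balanced sets provide the random control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grn_io import ROLE_BOTH, ROLE_REGULATOR, ROLE_TARGET

CLASS_COLUMN = "class"


def make_instances(discretized: pd.DataFrame) -> pd.DataFrame:
    """Expand a per-gene table (with a ``role`` column) into class-labeled instances.

    Genes with role ``both`` are duplicated into a regulator row and a target
    row; the index becomes ``gene_id`` plus the class is stored in the
    ``class`` column.  Instance ids are ``gene`` or ``gene::role`` for duals.
    """
    if "role" not in discretized.columns:
        raise ValueError("expected a 'role' column on the per-gene table")
    rows = []
    index = []
    feats = discretized.drop(columns=["role"])
    for gene, row in feats.iterrows():
        role = discretized.at[gene, "role"]
        if role == ROLE_BOTH:
            for r in (ROLE_REGULATOR, ROLE_TARGET):
                rows.append(list(row) + [r])
                index.append(f"{gene}::{r}")
        else:
            rows.append(list(row) + [role])
            index.append(str(gene))
    out = pd.DataFrame(rows, columns=list(feats.columns) + [CLASS_COLUMN], index=index)
    out.index.name = "instance_id"
    return out


@dataclass
class SplitResult:
    training: pd.DataFrame
    test: pd.DataFrame
    seed: int
    fraction: float


@dataclass
class BalancedSetCollection:
    sets: list[pd.DataFrame]
    seed: int
    manifest: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def split_train_test(
    table: pd.DataFrame, fraction: float = 0.10, seed: int = 0
) -> SplitResult:
    """Hold out ⌊fraction·#regulators⌋ regulators and as many targets, at random.

    The test set is exactly class-balanced; everything else is training.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    rng = np.random.default_rng(seed)
    reg_idx = table.index[table[CLASS_COLUMN] == ROLE_REGULATOR]
    tar_idx = table.index[table[CLASS_COLUMN] == ROLE_TARGET]
    if len(reg_idx) < 10:
        raise ValueError(f"need >= 10 regulator instances, got {len(reg_idx)}")
    n_test = math.floor(fraction * len(reg_idx))
    test_regs = rng.choice(reg_idx, size=n_test, replace=False)
    test_tars = rng.choice(tar_idx, size=n_test, replace=False)
    test_ids = np.concatenate([test_regs, test_tars])
    test = table.loc[test_ids]
    training = table.drop(index=test_ids)
    return SplitResult(training=training, test=test, seed=seed, fraction=fraction)


def make_balanced_sets(
    training: pd.DataFrame, seed: int = 0, *, drop_remainder: bool = False
) -> BalancedSetCollection:
    """Undersample targets into disjoint chunks, each joined with the regulators.

    Targets are shuffled and split into chunks of size R (the regulator
    count); each full chunk plus all R regulators forms one balanced set.  A
    final short chunk of r targets is, by default, joined with a random
    subsample of r regulators so the set stays exactly balanced
    (``drop_remainder=True`` discards it instead).  Rows within every set are
    shuffled before training.
    """
    rng = np.random.default_rng(seed)
    regs = training[training[CLASS_COLUMN] == ROLE_REGULATOR]
    tars = training[training[CLASS_COLUMN] == ROLE_TARGET]
    n_r, n_t = len(regs), len(tars)
    if n_r < 1:
        raise ValueError("no regulator instances in the training table")
    if n_t < n_r:
        raise ValueError(
            "more regulators than targets; swap which class is undersampled"
        )
    tar_order = tars.index.to_numpy()[rng.permutation(n_t)]
    sets: list[pd.DataFrame] = []
    sizes: list[int] = []
    for start in range(0, n_t, n_r):
        chunk = tar_order[start : start + n_r]
        if len(chunk) == n_r:
            members = np.concatenate([chunk, regs.index.to_numpy()])
        elif drop_remainder:
            continue
        else:
            sub = rng.choice(regs.index.to_numpy(), size=len(chunk), replace=False)
            members = np.concatenate([chunk, sub])
        s = training.loc[members]
        s = s.iloc[rng.permutation(len(s))]
        sets.append(s)
        sizes.append(len(s))
    manifest = {
        "seed": seed,
        "n_regulators": n_r,
        "n_targets": n_t,
        "set_sizes": sizes,
        "drop_remainder": drop_remainder,
    }
    return BalancedSetCollection(sets=sets, seed=seed, manifest=manifest)


def randomize_labels(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Shuffle only the class column, leaving every feature cell untouched.

    The class-frequency histogram is preserved exactly (a permutation).
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out[CLASS_COLUMN] = out[CLASS_COLUMN].to_numpy()[rng.permutation(len(out))]
    return out


def write_split_manifest(split: SplitResult, sets: BalancedSetCollection, path) -> None:
    manifest = {
        "split_seed": split.seed,
        "fraction": split.fraction,
        "n_training": len(split.training),
        "n_test": len(split.test),
        "test_ids": sorted(map(str, split.test.index)),
        "balanced_sets": sets.manifest,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
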