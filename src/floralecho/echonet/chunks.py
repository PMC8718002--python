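"""Echo chunk sampling and flower-stratified dataset splits.

A chunk is a set of k echoes from one flower presented to the classifier
simultaneously, emulating a bat integrating several calls during an approach.
Two sampling schemes are provided: *random* (echoes drawn from anywhere on
the angle grid, both planes pooled) and *interval* (echoes in angular
succession within one plane, every n-th response for a random n in 2..8,
mimicking a narrow approach trajectory; chunks are then internally redundant,
which is expected to hurt classification).

Splits are stratified per individual flower: all echoes of a flower land in
exactly one of train/validation/test, so test performance cannot be inflated
by echoes of already-seen flowers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ..sonar import ImpulseResponseScan

__all__ = ["EchoChunk", "DatasetSplit", "chunk_random", "chunk_interval", "split_by_flower"]

VALID_K = (1, 3, 5, 7, 10)


@dataclass(frozen=True)
class EchoChunk:
    """k echoes of one flower: references into its scans, plus the label."""

    flower_id: str
    species_id: str
    ir_refs: Tuple[Tuple[str, int], ...]  # (plane, angle index) per echo
    scheme: str  # "random" or "interval"

    @property
    def k(self) -> int:
        return len(self.ir_refs)


@dataclass(frozen=True)
class DatasetSplit:
    """Flower-ID lists per subset, keyed by species."""

    train: Dict[str, List[str]]
    val: Dict[str, List[str]]
    test: Dict[str, List[str]]

    def ids(self, subset: str) -> List[str]:
        return [fid for lst in getattr(self, subset).values() for fid in lst]

    def assert_disjoint(self) -> None:
        sets = {s: set(self.ids(s)) for s in ("train", "val", "test")}
        for a in sets:
            for b in sets:
                if a < b and sets[a] & sets[b]:
                    raise AssertionError(f"flower leakage between {a} and {b}")


def _pooled_refs(scans: Mapping[str, ImpulseResponseScan]) -> List[Tuple[str, int]]:
    refs = []
    for plane in sorted(scans):
        refs.extend((plane, i) for i in range(scans[plane].n_angles))
    return refs


def chunk_random(
    scans: Mapping[str, ImpulseResponseScan],
    species_id: str,
    k: int,
    rng: np.random.Generator,
) -> List[EchoChunk]:
    """Shuffle all of a flower's echoes (planes pooled) into groups of k.

    A final remainder smaller than k is dropped, so a 202-echo flower yields
    floor(202/k) chunks.
    """
    refs = _pooled_refs(scans)
    if len(refs) < k:
        raise ValueError(f"flower has {len(refs)} echoes; need at least k={k}")
    order = rng.permutation(len(refs))
    flower_id = next(iter(scans.values())).flower_id
    chunks = []
    for start in range(0, len(refs) - k + 1, k):
        sel = tuple(refs[i] for i in order[start : start + k])
        chunks.append(EchoChunk(flower_id, species_id, sel, "random"))
    return chunks


def chunk_interval(
    scans: Mapping[str, ImpulseResponseScan],
    species_id: str,
    k: int,
    rng: np.random.Generator,
    n_chunks: int = None,
    max_interval: int = 8,
) -> List[EchoChunk]:
    """Arithmetic-progression chunks within one plane's angular order.

    Each chunk draws a plane, an interval n in {2..max_interval} and a start
    index, then takes every n-th impulse response up to k items; draws whose
    run would exceed the scan end are rejected and redrawn (no wrap-around).
    The chunk count defaults to floor(total_echoes / k), matching
    :func:`chunk_random` for a fair comparison.
    """
    planes = sorted(scans)
    lengths = {p: scans[p].n_angles for p in planes}
    if all((k - 1) * 2 >= lengths[p] for p in planes):
        raise ValueError(
            f"no plane can fit k={k} echoes even at the minimum interval 2"
        )
    total = sum(lengths.values())
    if n_chunks is None:
        n_chunks = total // k
    flower_id = next(iter(scans.values())).flower_id
    chunks = []
    while len(chunks) < n_chunks:
        plane = planes[rng.integers(len(planes))]
        n = int(rng.integers(2, max_interval + 1))
        span = (k - 1) * n
        if span >= lengths[plane]:
            continue  # redraw: run would exceed the scan end
        start = int(rng.integers(0, lengths[plane] - span))
        refs = tuple((plane, start + j * n) for j in range(k))
        chunks.append(EchoChunk(flower_id, species_id, refs, "interval"))
    return chunks


def split_by_flower(
    flower_ids_by_species: Mapping[str, Sequence[str]],
    counts: Tuple[int, int, int] = (8, 2, 2),
    seed: int = 0,
    use_leftover_in_train: bool = False,
) -> DatasetSplit:
    """Per-species random assignment of whole flowers to train/val/test.

    Leftover flowers beyond sum(counts) are unused by default (with the
    default (8, 2, 2) counts and 14 flowers per species, 2 remain unused);
    set ``use_leftover_in_train`` to add them to the training set instead.
    """
    n_train, n_val, n_test = counts
    need = n_train + n_val + n_test
    rng = np.random.default_rng(seed)
    train: Dict[str, List[str]] = {}
    val: Dict[str, List[str]] = {}
    test: Dict[str, List[str]] = {}
    for species in sorted(flower_ids_by_species):
        ids = list(flower_ids_by_species[species])
        if len(ids) < need:
            raise ValueError(
                f"species {species} has {len(ids)} flowers; split needs {need}"
            )
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        train[species] = shuffled[:n_train]
        val[species] = shuffled[n_train : n_train + n_val]
        test[species] = shuffled[n_train + n_val : need]
        if use_leftover_in_train:
            train[species].extend(shuffled[need:])
    split = DatasetSplit(train=train, val=val, test=test)
    split.assert_disjoint()
    return split


def build_chunks(
    scans_by_flower: Mapping[str, Mapping[str, ImpulseResponseScan]],
    species_by_flower: Mapping[str, str],
    flower_ids: Sequence[str],
    k: int,
    scheme: str,
    seed: int,
) -> List[EchoChunk]:
    """Chunks for a list of flowers under one sampling scheme."""
    rng = np.random.default_rng(seed)
    chunker = {"random": chunk_random, "interval": chunk_interval}[scheme]
    chunks: List[EchoChunk] = []
    for fid in flower_ids:
        chunks.extend(chunker(scans_by_flower[fid], species_by_flower[fid], k, rng))
    return chunks
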