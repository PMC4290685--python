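"""Shared fixtures: synthetic datasets, toy proteins, random graphs."""

from __future__ import annotations

import numpy as np
import pytest

from patchkernel.features import (
    Atom,
    N_ATTRIBUTES,
    Protein,
    ResidueRecord,
    radius_for,
)
from patchkernel.graphs import LabeledGraph, shortest_path_transform
from patchkernel.synth import GeneratorConfig, generate_dataset


def make_protein(coords, attributes=None, *, protein_id="toy", asa_deltas=None,
                 rel_acc=None, radius=None):
    """Single-atom-per-residue protein from a list of 3D coordinates.

    ``asa_deltas`` sets asa_unbound − asa_complex per residue (asa_unbound is
    fixed at 100); ``rel_acc`` defaults to fully exposed.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if attributes is None:
        attributes = np.full((n, N_ATTRIBUTES), 0.5)
    if asa_deltas is None:
        asa_deltas = np.zeros(n)
    if rel_acc is None:
        rel_acc = np.full(n, 50.0)
    r = radius_for("C") if radius is None else radius
    residues = [
        ResidueRecord(
            protein_id=protein_id, chain="A", resnum=i + 1, icode="", aa="A",
            atoms=(Atom(name="CA", element="C", coords=coords[i], radius=r),),
            attributes=np.asarray(attributes[i], dtype=float),
            asa_complex=100.0 - float(asa_deltas[i]),
            asa_unbound=100.0,
            rel_acc=float(rel_acc[i]),
        )
        for i in range(n)
    ]
    return Protein(protein_id=protein_id, residues=residues)


def random_labeled_graph(rng, *, max_nodes=12, dim=3, p=None):
    """Random Erdős–Rényi labeled graph with labels in [0, 1]."""
    n = int(rng.integers(2, max_nodes + 1))
    p_edge = float(rng.uniform(0.1, 1.0)) if p is None else p
    edges = frozenset(
        (i, j) for i in range(n) for j in range(i + 1, n)
        if rng.random() < p_edge
    )
    labels = rng.random((n, dim))
    keys = tuple(("A", i + 1, "") for i in range(n))
    return LabeledGraph(keys=keys, labels=labels, edges=edges)


def random_sp_graph(rng, *, max_nodes=10, dim=3):
    """Random shortest-path graph with at least one weighted edge."""
    while True:
        g = shortest_path_transform(random_labeled_graph(rng, max_nodes=max_nodes,
                                                         dim=dim))
        if g.n_edges > 0:
            return g


@pytest.fixture(scope="session")
def separated_dataset():
    """20 proteins of 60 residues at full class separation (the conditions of
    the end-to-end discrimination check)."""
    config = GeneratorConfig(n_proteins=20, n_residues=60, separation=1.0,
                             noise_sd=0.15, seed=7)
    return [p for p, _ in generate_dataset(config)]


@pytest.fixture(scope="session")
def small_dataset():
    """Six 40-residue proteins at full separation, for fast pipeline tests."""
    config = GeneratorConfig(n_proteins=6, n_residues=40, separation=1.0,
                             noise_sd=0.15, seed=3)
    return [p for p, _ in generate_dataset(config)]
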