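"""Shipped circuit fixtures (TSV) and their loaders.

Every fixture can also be rebuilt programmatically from
:mod:`circuitsym.synthetic_data`; the TSV copies exist so the file I/O
path is exercised and users have ready-made inputs.  The ideal forward
circuit and the motor-block weights are reconstructions consistent with
the published block matrices, not measured data.
"""

from __future__ import annotations

from importlib import resources

from .circuits import Circuit, load_circuit

__all__ = ["fixture_path", "load_fixture", "FIXTURES"]

FIXTURES = (
    "command_unit",        # Eq-8-pattern 4-node command circuit (all links 1)
    "command_weighted",    # square-symmetric variant (pair 1 / cross 2)
    "forward_gap_ideal",   # 21-node ideal forward gap-junction circuit
    "backward_aib_rim",    # AIB/RIM backward block (two parallel junctions)
)


def fixture_path(name: str):
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    return resources.files("circuitsym").joinpath(f"data/{name}.tsv")


def load_fixture(name: str) -> Circuit:
    with resources.as_file(fixture_path(name)) as p:
        return load_circuit(p)
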