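"""Pluggable quantum-chemistry driver contract and the packaged results store.

The analysis pipeline consumes wavefunctions; producing them is delegated to
an external engine through a minimal contract: given element symbols,
coordinates and net charge, return a wavefunction file the readers in
:mod:`elfiqa.io` understand.  The package ships the cached output of one such
driver run — B3LYP (Gaussian convention, VWN3 correlation) / 6-31G(d)
optimized single-ring molecules — as compact JSON fixtures, so every
analysis in the test-suite and the worked examples is reproducible without a
QM engine on the machine.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Protocol

from .io import read_wavefunction
from .wavefunction import Wavefunction

__all__ = ["QMDriver", "FixtureStore", "load_molecule", "available_molecules"]


class QMDriver(Protocol):
    """Contract for an external engine producing single-determinant wavefunctions."""

    def run(self, symbols: list[str], coords_bohr, charge: int,
            workdir: Path) -> Path:
        """Optimize the geometry and return a wavefunction file path
        (Molden / wfn / wfx / elfiqa JSON)."""
        ...


class FixtureStore:
    """Packaged wavefunctions generated once by a B3LYP(VWN3)/6-31G(d) driver."""

    def __init__(self, root=None):
        self._root = root

    def _dir(self):
        if self._root is not None:
            return Path(self._root)
        return resources.files("elfiqa") / "data"

    def available(self) -> list[str]:
        return sorted(p.name[len("wf_"):-len(".json")]
                      for p in self._dir().glob("wf_*.json"))

    def load(self, name: str) -> Wavefunction:
        path = self._dir() / f"wf_{name}.json"
        if not path.is_file():
            raise FileNotFoundError(
                f"no packaged wavefunction {name!r}; available: {self.available()}")
        return read_wavefunction(path, format="json")


_DEFAULT_STORE = FixtureStore()


def available_molecules() -> list[str]:
    return _DEFAULT_STORE.available()


def load_molecule(name: str) -> Wavefunction:
    """Load a packaged B3LYP(VWN3)/6-31G(d) wavefunction by molecule name."""
    return _DEFAULT_STORE.load(name)
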