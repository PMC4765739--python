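"""Parameter and state containers for the calnexin palmitoylation network.

The network has five protein states: newly synthesized calnexin (``rCAL``),
folded non-palmitoylated calnexin (``fCAL``), the two singly palmitoylated
species (``c1CAL``, ``c2CAL``) and the dually palmitoylated species
(``c12CAL``).  Concentrations are in arbitrary units normalized so that the
wild-type steady-state total is 1; time is in hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

SPECIES = ("rCAL", "fCAL", "c1CAL", "c2CAL", "c12CAL")
R, F, C1, C2, C12 = range(5)

#: Names of the four palmitoylation reactions, in canonical order:
#: p1: fCAL -> c1CAL, p2: fCAL -> c2CAL, p12: c1CAL -> c12CAL,
#: p21: c2CAL -> c12CAL.
PALM_REACTIONS = ("p1", "p2", "p12", "p21")

#: Depalmitoylation reactions: d1: c1CAL -> fCAL, d2: c2CAL -> fCAL,
#: d121: c12CAL -> c2CAL (site-1 removal), d122: c12CAL -> c1CAL
#: (site-2 removal).
DEPALM_REACTIONS = ("d1", "d2", "d121", "d122")


@dataclass(frozen=True)
class SpeciesVector:
    """Abundances of the five calnexin states (arbitrary units)."""

    rCAL: float = 0.0
    fCAL: float = 0.0
    c1CAL: float = 0.0
    c2CAL: float = 0.0
    c12CAL: float = 0.0

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("species abundances must be finite")
        if np.any(arr < 0):
            raise ValueError("species abundances must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.rCAL, self.fCAL, self.c1CAL, self.c2CAL, self.c12CAL], float
        )

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "SpeciesVector":
        a = np.asarray(arr, float)
        return cls(*a.tolist())

    def total(self) -> float:
        return float(self.to_array().sum())


_PARAM_FIELDS = (
    "v_syn", "k_fold",
    "kcat_p1", "kcat_p2", "kcat_p12", "kcat_p21",
    "Km_p1", "Km_p2", "Km_p12", "Km_p21",
    "kcat_d1", "kcat_d2", "kcat_d121", "kcat_d122",
    "Km_d1", "Km_d2", "Km_d121", "Km_d122",
    "kdeg_r", "kdeg_f", "kdeg_c1", "kdeg_c2", "kdeg_c12",
    "E_pat", "E_apt",
)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the palmitoylation cycle.

    Units: ``v_syn`` a.u./h (zero order); catalytic and first-order
    constants 1/h; Michaelis constants and enzyme totals a.u.  ``E_pat``
    is the total DHHC6 palmitoyltransferase, ``E_apt`` the lumped acyl
    protein thioesterase pool.
    """

    v_syn: float
    k_fold: float
    kcat_p1: float
    kcat_p2: float
    kcat_p12: float
    kcat_p21: float
    Km_p1: float
    Km_p2: float
    Km_p12: float
    Km_p21: float
    kcat_d1: float
    kcat_d2: float
    kcat_d121: float
    kcat_d122: float
    Km_d1: float
    Km_d2: float
    Km_d121: float
    Km_d122: float
    kdeg_r: float
    kdeg_f: float
    kdeg_c1: float
    kdeg_c2: float
    kdeg_c12: float
    E_pat: float
    E_apt: float

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f_.name} must be positive and finite")

    # -- array round-trip ----------------------------------------------------
    names = _PARAM_FIELDS

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_FIELDS], float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "KineticParameters":
        a = np.asarray(arr, float)
        if a.shape != (len(_PARAM_FIELDS),):
            raise ValueError(f"expected {len(_PARAM_FIELDS)} parameters")
        return cls(**dict(zip(_PARAM_FIELDS, a.tolist())))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in _PARAM_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**{n: float(d[n]) for n in _PARAM_FIELDS})

    def replace(self, **kw) -> "KineticParameters":
        return replace(self, **kw)

    def tie_kdeg_rf(self) -> "KineticParameters":
        """Variant with kdeg_r tied to kdeg_f (a 14-reaction reading of the
        network in which unfolded and folded calnexin degrade identically)."""
        return replace(self, kdeg_r=self.kdeg_f)

    # -- plain-text config ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=1)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "KineticParameters":
        path = Path(path)
        d = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls.from_dict(d)


MUTANTS = ("WT", "AC", "CA", "AA")

# Mask over (p1, p2, p12, p21): AC ablates site 1 (p1, p21), CA ablates
# site 2 (p2, p12), AA ablates everything.
_MUTANT_MASKS = {
    "WT": np.array([1.0, 1.0, 1.0, 1.0]),
    "AC": np.array([0.0, 1.0, 1.0, 0.0]),
    "CA": np.array([1.0, 0.0, 0.0, 1.0]),
    "AA": np.array([0.0, 0.0, 0.0, 0.0]),
}


@dataclass(frozen=True)
class Perturbation:
    """Experimental condition applied to the network.

    ``pat_scale`` multiplies the DHHC6 total (0.1 emulates silencing, 10
    overexpression); ``synthesis_on`` gates the zero-order synthesis flux;
    ``mutant`` removes palmitoylation sites (AC keeps only site 2, CA only
    site 1, AA neither).
    """

    pat_scale: float = 1.0
    synthesis_on: bool = True
    mutant: str = "WT"

    def __post_init__(self) -> None:
        if self.pat_scale < 0:
            raise ValueError("pat_scale must be >= 0")
        if self.mutant not in MUTANTS:
            raise ValueError(f"mutant must be one of {MUTANTS}")

    @property
    def palm_mask(self) -> np.ndarray:
        return _MUTANT_MASKS[self.mutant]


WT = Perturbation()
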