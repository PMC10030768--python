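"""Spectrum definitions for backbone triple-resonance experiments.

Every experiment considered here is rooted at a backbone amide: each crosspeak
carries the amide ¹H and ¹⁵N shifts of residue i plus (for 3D experiments) one
carbon shift belonging either to residue i or to its predecessor i-1.  A
dimension whose resonance could be either the (i) or the (i-1) nucleus is
*ambiguous*; the candidate peak types below enumerate the possibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Backbone resonance labels.  The "-1" suffix marks an (i-1) resonance, i.e.
#: a nucleus belonging to the residue preceding the amide that roots the peak.
RESONANCES = ("H", "N", "CA", "CB", "CO")
PREV_SUFFIX = "-1"
ALL_LABELS = RESONANCES + tuple(r + PREV_SUFFIX for r in ("CA", "CB", "CO"))

#: Default shift-matching tolerances in ppm per nucleus class.
DEFAULT_TOLERANCES = {"H": 0.03, "N": 0.3, "C": 0.3}


def base_resonance(label: str) -> str:
    """Strip the (i-1) suffix: ``CA-1`` -> ``CA``."""
    return label[:-len(PREV_SUFFIX)] if label.endswith(PREV_SUFFIX) else label


def is_prev(label: str) -> bool:
    return label.endswith(PREV_SUFFIX)


def nucleus_of(label: str) -> str:
    """Nucleus class (H, N or C) of a resonance label."""
    base = base_resonance(label)
    return base if base in ("H", "N") else "C"


@dataclass(frozen=True)
class SpectrumDefinition:
    """One triple-resonance (or HSQC) experiment type.

    Parameters
    ----------
    name:
        Experiment identifier, e.g. ``"HNCA"``.
    dimensions:
        Ordered nucleus classes of the spectral dimensions, e.g.
        ``("H", "N", "C")``.
    candidate_peak_types:
        The resonance-type tuples a crosspeak from this experiment can
        represent; arity matches the dimension count.
    match_tolerances:
        Per-dimension shift-matching cutoffs in ppm used during spin-system
        assembly.
    """

    name: str
    dimensions: tuple[str, ...]
    candidate_peak_types: tuple[tuple[str, ...], ...]
    match_tolerances: tuple[float, ...] = field(default=())

    def __post_init__(self):
        tols = self.match_tolerances or tuple(
            DEFAULT_TOLERANCES[d] for d in self.dimensions
        )
        object.__setattr__(self, "match_tolerances", tols)
        if len(tols) != len(self.dimensions):
            raise ValueError(f"{self.name}: one tolerance per dimension required")
        if any(t <= 0 for t in tols):
            raise ValueError(f"{self.name}: tolerances must be strictly positive")
        for cand in self.candidate_peak_types:
            if len(cand) != len(self.dimensions):
                raise ValueError(
                    f"{self.name}: candidate type {cand} does not match "
                    f"dimensionality {len(self.dimensions)}"
                )
            for lab, dim in zip(cand, self.dimensions):
                if nucleus_of(lab) != dim:
                    raise ValueError(
                        f"{self.name}: label {lab} incompatible with {dim} dimension"
                    )

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    @property
    def h_dim(self) -> int:
        return self.dimensions.index("H")

    @property
    def n_dim(self) -> int:
        return self.dimensions.index("N")

    @property
    def carbon_dims(self) -> tuple[int, ...]:
        return tuple(i for i, d in enumerate(self.dimensions) if d == "C")


def _spec(name, candidates):
    ndim = len(candidates[0])
    dims = ("H", "N", "C")[:ndim]
    return SpectrumDefinition(name, dims, tuple(candidates))


#: The canonical amide-rooted experiment set.
CANONICAL_SPECTRA: dict[str, SpectrumDefinition] = {
    s.name: s
    for s in (
        _spec("HSQC", [("H", "N")]),
        _spec("HNCO", [("H", "N", "CO-1")]),
        _spec("HNCACO", [("H", "N", "CO"), ("H", "N", "CO-1")]),
        _spec("HNCA", [("H", "N", "CA"), ("H", "N", "CA-1")]),
        _spec("HNCOCA", [("H", "N", "CA-1")]),
        _spec(
            "HNCACB",
            [("H", "N", "CA"), ("H", "N", "CB"), ("H", "N", "CA-1"), ("H", "N", "CB-1")],
        ),
        _spec("CBCACONH", [("H", "N", "CA-1"), ("H", "N", "CB-1")]),
    )
}

#: Aliases matching common experiment spellings.
SPECTRUM_ALIASES = {
    "HN(CA)CO": "HNCACO",
    "HN(CO)CA": "HNCOCA",
    "HN(CO)CACB": "CBCACONH",
    "CBCA(CO)NH": "CBCACONH",
}


def get_spectrum(name: str) -> SpectrumDefinition:
    key = name.upper()
    key = SPECTRUM_ALIASES.get(key, key)
    try:
        return CANONICAL_SPECTRA[key]
    except KeyError:
        raise KeyError(
            f"unknown spectrum {name!r}; known: {sorted(CANONICAL_SPECTRA)}"
        ) from None
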