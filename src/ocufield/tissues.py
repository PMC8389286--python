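"""Tissue conductivity tables for low-frequency (10 Hz) electrical stimulation.

At 10 Hz the quasi-static approximation holds: capacitive and inductive
effects are negligible and each tissue is characterised by a single real,
isotropic conductivity in S/m.
"""
from __future__ import annotations

from typing import Dict, Mapping

__all__ = [
    "ConductivityTable",
    "default_conductivities",
    "TISSUES",
]

#: Canonical tissue names of the six-compartment head model, ordered from
#: the innermost layer outward, with the eyeballs last.
TISSUES = ("white_matter", "gray_matter", "csf", "bone", "skin", "eyeball")

# Reference conductivities (S/m) for 10 Hz stimulation.  Note the head-skin
# value is several orders of magnitude below most literature tables; it is
# kept verbatim as the reference condition, and callers may override it
# explicitly via ConductivityTable(overrides=...).
_DEFAULT = {
    "white_matter": 0.027656,
    "gray_matter": 0.027512,
    "csf": 2.0000,
    "bone": 0.020028,
    "skin": 2.0000e-4,
    "eyeball": 0.41113,
}


class ConductivityTable:
    """Mapping tissue name -> electrical conductivity in S/m.

    All values must be strictly positive.  Behaves like a read-only mapping;
    ``sigma_for_labels`` vectorises the lookup over an integer-coded label
    array (as stored on a :class:`~ocufield.meshing.VolumeMesh`).
    """

    def __init__(self, values: Mapping[str, float] | None = None,
                 overrides: Mapping[str, float] | None = None):
        base: Dict[str, float] = dict(_DEFAULT) if values is None else dict(values)
        if overrides:
            base.update(overrides)
        for name, sigma in base.items():
            if not sigma > 0:
                raise ValueError(
                    f"conductivity for {name!r} must be > 0, got {sigma}")
        self._values = base

    def __getitem__(self, tissue: str) -> float:
        return self._values[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self._values

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def items(self):
        return self._values.items()

    def as_dict(self) -> Dict[str, float]:
        return dict(self._values)

    def sigma_for_labels(self, labels, label_names: Mapping[int, str]):
        """Per-element sigma for integer-coded ``labels``.

        Raises ``KeyError`` if any label name is missing from the table.
        """
        import numpy as np

        lut = {}
        for code, name in label_names.items():
            if name not in self._values:
                raise KeyError(
                    f"tissue {name!r} (label {code}) has no conductivity entry")
            lut[code] = self._values[name]
        out = np.empty(len(labels), dtype=float)
        labels = np.asarray(labels)
        for code, sigma in lut.items():
            out[labels == code] = sigma
        unknown = set(np.unique(labels)) - set(lut)
        if unknown:
            raise KeyError(f"mesh labels {sorted(unknown)} missing from label_names")
        return out

    def __repr__(self) -> str:  # pragma: no cover
        body = ", ".join(f"{k}={v:g}" for k, v in self._values.items())
        return f"ConductivityTable({body})"


def default_conductivities() -> ConductivityTable:
    """The reference six-tissue table for 10 Hz stimulation."""
    return ConductivityTable()
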