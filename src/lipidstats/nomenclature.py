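"""Shotgun-lipidomics shorthand nomenclature.

Species are reported by the upstream identification software as a class
token followed by the summed fatty-acyl composition, e.g. ``LPE 22:6``
(lysophosphatidylethanolamine, 22 acyl carbons, 6 C=C double bonds) or
``PE O-38:5`` (ether-linked phosphatidylethanolamine).  The parser turns
such names into structural features — class, total carbons, total double
bonds, lyso/ether flags — that every downstream statistic consumes.

The class registry is data, not code: instrument configurations differ in
which classes they monitor, so additional classes can be registered at run
time or loaded from a YAML mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "LipidClassInfo",
    "LipidSpecies",
    "LipidParseError",
    "UnknownLipidClassError",
    "MalformedSpeciesNameError",
    "DEFAULT_REGISTRY",
    "default_registry",
    "register_class",
    "registry_from_mapping",
    "parse_species",
    "format_species",
    "is_saturated",
]


class LipidParseError(ValueError):
    """Base class for species-name parse failures; carries the bad name."""

    def __init__(self, name: str, message: str):
        self.name = name
        super().__init__(f"{message!s}: {name!r}")


class UnknownLipidClassError(LipidParseError):
    """The leading class token is not in the registry."""


class MalformedSpeciesNameError(LipidParseError):
    """The carbons:double-bonds field is missing, non-integer or invalid."""


@dataclass(frozen=True)
class LipidClassInfo:
    """Structural properties shared by all species of a lipid class."""

    code: str
    is_lyso: bool = False
    is_ether: bool = False
    is_sphingolipid: bool = False
    is_sterol_ester: bool = False


def _cls(code, **kw):
    return LipidClassInfo(code=code, **kw)


#: Classes monitored by the quadrupole/Orbitrap shotgun platform the study
#: data come from.  Extensible via :func:`register_class`.
DEFAULT_REGISTRY: dict[str, LipidClassInfo] = {
    c.code: c
    for c in [
        _cls("CE", is_sterol_ester=True),
        _cls("DAG"),
        _cls("TAG"),
        _cls("PC"),
        _cls("PC O-", is_ether=True),
        _cls("PE"),
        _cls("PE O-", is_ether=True),
        _cls("PS"),
        _cls("PI"),
        _cls("PA"),
        _cls("PG"),
        _cls("CL"),
        _cls("LPA", is_lyso=True),
        _cls("LPC", is_lyso=True),
        _cls("LPC O-", is_lyso=True, is_ether=True),
        _cls("LPE", is_lyso=True),
        _cls("LPE O-", is_lyso=True, is_ether=True),
        _cls("LPI", is_lyso=True),
        _cls("LPS", is_lyso=True),
        _cls("Cer", is_sphingolipid=True),
        _cls("HexCer", is_sphingolipid=True),
        _cls("SM", is_sphingolipid=True),
    ]
}


def default_registry() -> dict[str, LipidClassInfo]:
    """A fresh copy of the built-in class registry."""
    return dict(DEFAULT_REGISTRY)


def register_class(
    registry: dict[str, LipidClassInfo], info: LipidClassInfo
) -> dict[str, LipidClassInfo]:
    """Add (or replace) a class in ``registry``; returns the registry."""
    registry[info.code] = info
    return registry


def registry_from_mapping(
    mapping: Mapping[str, Mapping[str, bool]],
    base: Mapping[str, LipidClassInfo] | None = None,
) -> dict[str, LipidClassInfo]:
    """Build a registry from a plain mapping (e.g. parsed from YAML).

    ``mapping`` maps class codes to flag dicts, e.g.
    ``{"GM3": {"is_sphingolipid": true}}``.  Entries extend (and may
    override) ``base``, which defaults to the built-in registry.
    """
    reg = dict(DEFAULT_REGISTRY if base is None else base)
    for code, flags in mapping.items():
        reg[code] = LipidClassInfo(code=code, **dict(flags))
    return reg


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition lipid species.

    ``total_carbons`` and ``total_double_bonds`` are summed over all fatty
    acyl chains; sn-position or per-chain composition is not represented.
    ``extra_suffix`` stores a trailing ``;n`` hydroxylation field verbatim;
    it is ignored by all statistics.
    """

    raw_name: str
    class_info: LipidClassInfo
    total_carbons: int
    total_double_bonds: int
    extra_suffix: str = ""

    def __post_init__(self):
        if self.total_carbons < 1:
            raise MalformedSpeciesNameError(self.raw_name, "total carbons must be >= 1")
        if self.total_double_bonds < 0:
            raise MalformedSpeciesNameError(self.raw_name, "double bonds must be >= 0")
        if self.total_double_bonds >= self.total_carbons:
            raise MalformedSpeciesNameError(
                self.raw_name, "double bonds must be fewer than carbons"
            )

    def format(self) -> str:
        """Canonical shorthand: ``PE O-38:5`` / ``LPE 22:6`` (+ suffix)."""
        code = self.class_info.code
        sep = "" if code.endswith("O-") else " "
        return f"{code}{sep}{self.total_carbons}:{self.total_double_bonds}{self.extra_suffix}"


_CD_RE = re.compile(r"^(\d+):(\d+)(;\d+)?$")


def parse_species(
    name: str, registry: Mapping[str, LipidClassInfo] | None = None
) -> LipidSpecies:
    """Parse a shorthand species name into its structural features.

    The class token is matched greedily (longest registry code first), so
    ``LPE O-18:1`` resolves to the ether-lyso class and never to ``LPE``.
    Both ``PE O-38:5`` and ``PE O- 38:5`` dialects are accepted; the
    canonical form emitted by :meth:`LipidSpecies.format` is space-free
    after the ``O-`` marker.

    Raises
    ------
    UnknownLipidClassError
        No registry code prefixes ``name``.
    MalformedSpeciesNameError
        The ``carbons:doublebonds`` field is absent or invalid.
    """
    reg = DEFAULT_REGISTRY if registry is None else registry
    if not isinstance(name, str) or not name.strip():
        raise MalformedSpeciesNameError(str(name), "empty species name")
    stripped = name.strip()

    match_code = None
    for code in sorted(reg, key=len, reverse=True):
        if stripped == code or (
            stripped.startswith(code)
            and (code.endswith("O-") or stripped[len(code) :].startswith(" "))
        ):
            match_code = code
            break
    if match_code is None:
        raise UnknownLipidClassError(name, "unknown lipid class token")

    rest = stripped[len(match_code) :]
    if rest.startswith(" "):
        rest = rest[1:]
    m = _CD_RE.match(rest)
    if m is None:
        raise MalformedSpeciesNameError(name, "malformed carbons:doublebonds field")
    carbons, db, suffix = int(m.group(1)), int(m.group(2)), m.group(3) or ""
    return LipidSpecies(
        raw_name=stripped,
        class_info=reg[match_code],
        total_carbons=carbons,
        total_double_bonds=db,
        extra_suffix=suffix,
    )


def format_species(sp: LipidSpecies) -> str:
    """Canonical shorthand for ``sp`` (see :meth:`LipidSpecies.format`)."""
    return sp.format()


def is_saturated(sp: LipidSpecies) -> bool:
    """True iff the species carries no C=C double bond in any acyl chain."""
    return sp.total_double_bonds == 0
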