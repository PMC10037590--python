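"""Registry of diagnosis, procedure, and trauma code sets with prefix matching.

Hip fractures are coded S72.0/S72.1/S72.2 (ICD-10-CA) with CCI procedures
for fixation (1VA74, 1VC74), reduction (1VA73, 1VC73), repair (1VA80,
1VC80), and replacement (1VA53).  Radius/ulna fractures are coded S52.x
(ICD-10-CA) or OHIP fee code 813 in outpatient claims, with CCI procedures
for fixation (1TV74), reduction (1TV73), immobilization (1TV03), and repair
(1TV80, 1TV82).  External-cause (trauma) codes are the ICD-10-CA "V" and
"W" chapters: transport accidents and falls/exposure to mechanical forces.

Patterns are stored normalized (uppercase, dot-free); a trailing wildcard
in the usual clinical shorthand ("S72.0x") becomes a prefix pattern.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from .claims_model import normalize_code

__all__ = [
    "CodePattern",
    "CodeSet",
    "CodeSetError",
    "default_registry",
    "matches",
    "derive_variant",
    "write_registry",
    "read_registry",
]


class CodeSetError(ValueError):
    """Registry misconfiguration (unknown set or pattern name, duplicates)."""


@dataclass(frozen=True)
class CodePattern:
    pattern: str
    match_mode: str = "prefix"  # or "exact"
    code_system: str = "ICD10CA"  # ICD10CA | CCI | OHIP_FEE

    def __post_init__(self) -> None:
        if not self.pattern or self.pattern != self.pattern.upper() or "." in self.pattern:
            raise ValueError(f"pattern {self.pattern!r} is not normalized")
        if self.match_mode not in ("prefix", "exact"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, code: str, code_system: str) -> bool:
        if code_system != self.code_system:
            return False
        if self.match_mode == "exact":
            return code == self.pattern
        return code.startswith(self.pattern)


@dataclass(frozen=True)
class CodeSet:
    name: str
    site: str  # hip | radius_ulna | any
    role: str  # diagnosis | procedure | trauma
    patterns: tuple[CodePattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"code set {self.name} has no patterns")
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError(f"code set {self.name} has duplicate patterns")


Registry = Mapping[str, CodeSet]


def _dx(p: str) -> CodePattern:
    return CodePattern(normalize_code(p), "prefix", "ICD10CA")


def _px(p: str) -> CodePattern:
    return CodePattern(normalize_code(p), "prefix", "CCI")


def default_registry() -> dict[str, CodeSet]:
    """The built-in code sets for hip and radius/ulna fracture ascertainment."""
    return {
        "hip_dx": CodeSet("hip_dx", "hip", "diagnosis", (_dx("S72.0x"), _dx("S72.1x"), _dx("S72.2x"))),
        "hip_px": CodeSet(
            "hip_px",
            "hip",
            "procedure",
            (_px("1VA74"), _px("1VC74"), _px("1VA73"), _px("1VC73"), _px("1VA80"), _px("1VC80"), _px("1VA53")),
        ),
        "hip_subtrochanteric": CodeSet("hip_subtrochanteric", "hip", "diagnosis", (_dx("S72.2x"),)),
        "hip_replacement": CodeSet("hip_replacement", "hip", "procedure", (_px("1VA53"),)),
        "radius_dx_icd": CodeSet("radius_dx_icd", "radius_ulna", "diagnosis", (_dx("S52.x"),)),
        "radius_dx_fee": CodeSet(
            "radius_dx_fee", "radius_ulna", "diagnosis", (CodePattern("813", "exact", "OHIP_FEE"),)
        ),
        "radius_px": CodeSet(
            "radius_px", "radius_ulna", "procedure",
            (_px("1TV74"), _px("1TV73"), _px("1TV03"), _px("1TV80"), _px("1TV82")),
        ),
        "trauma": CodeSet("trauma", "any", "trauma", (_dx("V"), _dx("W"))),
    }


def matches(code: str, code_system: str, codeset: CodeSet) -> bool:
    """True iff some pattern of the set, in the same code system, matches."""
    return any(p.matches(code, code_system) for p in codeset.patterns)


def derive_variant(registry: Registry, drop: Iterable[str]) -> dict[str, CodeSet]:
    """Return a registry with the named patterns (or whole sets) removed.

    Names may be code-set names ("hip_replacement") or pattern strings
    ("S722", "1VA53"); a pattern name is removed from every set that carries
    it.  The input registry is left untouched.  A set whose patterns are all
    dropped is removed entirely.
    """
    drop = list(drop)
    known = set(registry) | {p.pattern for cs in registry.values() for p in cs.patterns}
    unknown = [name for name in drop if name not in known]
    if unknown:
        raise CodeSetError(f"unknown set/pattern name(s): {', '.join(unknown)}")

    set_drops = {name for name in drop if name in registry}
    pattern_drops = {name for name in drop} - set_drops

    out: dict[str, CodeSet] = {}
    for name, cs in registry.items():
        if name in set_drops:
            continue
        kept = tuple(p for p in cs.patterns if p.pattern not in pattern_drops)
        if kept:
            out[name] = CodeSet(cs.name, cs.site, cs.role, kept)
    return out


REGISTRY_COLUMNS = ["name", "site", "role", "code_system", "match_mode", "pattern"]


def write_registry(registry: Registry, path) -> None:
    """Serialize a registry to CSV (one row per pattern) so users can swap in
    jurisdiction-specific code lists."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(REGISTRY_COLUMNS)
        for cs in registry.values():
            for p in cs.patterns:
                writer.writerow([cs.name, cs.site, cs.role, p.code_system, p.match_mode, p.pattern])


def read_registry(path) -> dict[str, CodeSet]:
    rows: dict[str, dict] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        missing = [c for c in REGISTRY_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise CodeSetError(f"{path}: missing column(s) {', '.join(missing)}")
        for row in reader:
            entry = rows.setdefault(row["name"], {"site": row["site"], "role": row["role"], "patterns": []})
            entry["patterns"].append(CodePattern(row["pattern"], row["match_mode"], row["code_system"]))
    return {
        name: CodeSet(name, spec["site"], spec["role"], tuple(spec["patterns"]))
        for name, spec in rows.items()
    }
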