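"""Clinical code registry with explicit matching semantics.

Every diagnosis, drug-class, and procedure list used by the case-definition
engine lives here as *data*, loaded from a YAML config, so a site can swap
its own code lists without touching the engine.

Diagnosis codes are ICD-9-CM.  Codes are normalized to decimal-free strings
("250.13" -> "25013") and patterns match by prefix at the three-digit family
boundary or deeper.  One refinement keeps enumerated lists faithful: when a
set contains both a pattern and one of its proper extensions (e.g. "250"
alongside "2500", "2501", ...), the shorter pattern matches *exactly* only —
the set is read as enumerating the subcategories it intends, so "250, 250.0,
250.1, 250.2, 250.3, 250.9" does not swallow 250.4x–250.8x.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "CodeRegistry",
    "CodesetError",
    "MalformedCodeError",
    "normalize_code",
    "match_code",
    "load_registry",
    "default_registry",
]


class CodesetError(ValueError):
    """Raised when a registry config is missing a set or violates an invariant."""


class MalformedCodeError(ValueError):
    """Raised when a claim carries a code that is empty after normalization."""


def normalize_code(code: str, *, is_diagnosis: bool = True) -> str:
    """Normalize a raw code string for matching.

    Strips whitespace, uppercases, and (for diagnosis codes) removes a single
    embedded decimal point, so "250.13" and "25013" are the same code.
    """
    if code is None:
        raise MalformedCodeError("code is None")
    c = str(code).strip().upper()
    if is_diagnosis:
        c = c.replace(".", "", 1)
    if not c or any(ch.isspace() for ch in c):
        raise MalformedCodeError(f"malformed code {code!r}")
    return c


def _normalize_patterns(patterns: Iterable[str], *, is_diagnosis: bool = True) -> frozenset[str]:
    out = set()
    for p in patterns:
        out.add(normalize_code(p, is_diagnosis=is_diagnosis))
    return frozenset(out)


def match_code(pattern_set: Iterable[str], code: str, *, is_diagnosis: bool = True) -> bool:
    """True iff ``code`` is matched by ``pattern_set``.

    A pattern matches its own exact code and, by prefix, any code extending
    it with trailing characters — unless the set also contains a proper
    extension of that pattern, in which case the shorter pattern is exact-only
    (the set enumerates its subcategories).  Diagnosis patterns shorter than
    the 3-digit family boundary never match by prefix.
    """
    c = normalize_code(code, is_diagnosis=is_diagnosis)
    pats = pattern_set if isinstance(pattern_set, frozenset) else frozenset(
        normalize_code(p, is_diagnosis=is_diagnosis) for p in pattern_set
    )
    for p in pats:
        if c == p:
            return True
        if len(p) >= 3 and c.startswith(p):
            # exact-only if the set refines p further
            if any(q != p and q.startswith(p) for q in pats):
                continue
            return True
    return False


_DX_FIELDS = (
    "dx_diabetes_primary_inpatient",
    "dx_diabetes_general",
    "dx_pcos",
    "dx_menses_abnormal",
)
_PROC_FIELDS = (
    "proc_diabetes_management",
    "proc_glycosylated_hemoglobin",
    "proc_diabetes_related",
)
_DRUG_FIELDS = ("drug_insulin", "drug_insulin_adjunct", "drug_oral_hypoglycemic")

_DIABETES_DRUG_CLASSES = frozenset({"insulin", "insulin_adjunct", "oral_hypoglycemic"})


class CodeRegistry(BaseModel):
    """Named, validated sets of code patterns driving the case definition.

    Diagnosis sets hold decimal-free ICD-9-CM prefixes; drug sets hold the
    closed drug-class vocabulary of the prescription table; procedure sets
    hold procedure-code prefixes (HCPCS/CPT-style strings).
    """

    model_config = {"frozen": True}

    name: str = "default"
    dx_diabetes_primary_inpatient: frozenset[str]
    dx_diabetes_general: frozenset[str]
    dx_pcos: frozenset[str]
    dx_menses_abnormal: frozenset[str]
    drug_insulin: frozenset[str]
    drug_insulin_adjunct: frozenset[str]
    drug_oral_hypoglycemic: frozenset[str]
    proc_diabetes_management: frozenset[str]
    proc_glycosylated_hemoglobin: frozenset[str]
    proc_diabetes_related: frozenset[str]

    @field_validator(*_DX_FIELDS, mode="before")
    @classmethod
    def _norm_dx(cls, v):
        if not v:
            raise CodesetError("code set must be non-empty")
        return _normalize_patterns(v, is_diagnosis=True)

    @field_validator(*_PROC_FIELDS, *_DRUG_FIELDS, mode="before")
    @classmethod
    def _norm_other(cls, v):
        if not v:
            raise CodesetError("code set must be non-empty")
        return _normalize_patterns(v, is_diagnosis=False)

    @model_validator(mode="after")
    def _invariants(self):
        for p in self.dx_diabetes_primary_inpatient:
            if not match_code(self.dx_diabetes_general, p):
                raise CodesetError(
                    "dx_diabetes_primary_inpatient must be a subset of "
                    f"dx_diabetes_general (pattern {p!r} is not covered)"
                )
        for p in self.proc_glycosylated_hemoglobin:
            if not match_code(self.proc_diabetes_management, p, is_diagnosis=False):
                raise CodesetError(
                    "proc_glycosylated_hemoglobin must be a subset of "
                    f"proc_diabetes_management (pattern {p!r} is not covered)"
                )
        return self

    # -- convenience predicates used throughout the engine -----------------

    def is_diabetes_dx(self, code: str) -> bool:
        return match_code(self.dx_diabetes_general, code)

    def is_primary_inpatient_dx(self, code: str) -> bool:
        return match_code(self.dx_diabetes_primary_inpatient, code)

    def is_pcos_dx(self, code: str) -> bool:
        return match_code(self.dx_pcos, code)

    def is_menses_abnormal_dx(self, code: str) -> bool:
        return match_code(self.dx_menses_abnormal, code)

    def is_diabetes_drug_class(self, drug_class: str) -> bool:
        return drug_class in _DIABETES_DRUG_CLASSES

    def is_management_proc(self, code: str) -> bool:
        return match_code(self.proc_diabetes_management, code, is_diagnosis=False)

    def is_hba1c_proc(self, code: str) -> bool:
        return match_code(self.proc_glycosylated_hemoglobin, code, is_diagnosis=False)

    def is_index_reset_proc(self, code: str) -> bool:
        return match_code(self.proc_diabetes_related, code, is_diagnosis=False)


def _default_config_path() -> Path:
    return Path(str(resources.files("phenotyper").joinpath("data/codesets_default.yaml")))


def load_registry(config_path: str | Path | None = None) -> CodeRegistry:
    """Load a :class:`CodeRegistry` from YAML; ``None`` loads the shipped default.

    The YAML has one key per registry field; any field may be overridden by a
    site-specific file (missing fields fall back to the shipped defaults).
    """
    defaults = yaml.safe_load(_default_config_path().read_text())
    data = dict(defaults)
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"registry config not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        if not isinstance(user, dict):
            raise CodesetError(f"registry config {path} must be a mapping")
        unknown = set(user) - set(CodeRegistry.model_fields)
        if unknown:
            raise CodesetError(f"unknown registry keys: {sorted(unknown)}")
        data.update(user)
    try:
        return CodeRegistry(**data)
    except CodesetError:
        raise
    except Exception as exc:  # pydantic ValidationError -> config error
        raise CodesetError(str(exc)) from exc


def default_registry() -> CodeRegistry:
    """The registry shipped with the package (Tennessee-Medicaid-style defaults)."""
    return load_registry(None)
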