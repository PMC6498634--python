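"""The 29 clinical categories and the ICD9-CM → category mapping.

The analysis reduces every emergency-department diagnosis or trauma to one of
29 categories: 9 specific violence diagnoses (matched exactly by ICD9-CM
code), 13 named diagnostic groups with a previously reported association with
gender-based violence, a residual other-diagnoses group, a missing-diagnosis
category (visits where the woman left before being examined), and 5 trauma
groups (repeated aggression plus unintentional traumas by place of
occurrence).

The group boundaries for the 13 named diagnostic groups are ICD9-CM chapter
ranges shipped as a versioned config file (``data/icd9_groups.yaml``); a user
holding a different grouping can substitute their own table via
:class:`CategoryMapper`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "CATEGORIES",
    "N_CATEGORIES",
    "VIOLENCE_CODES",
    "VIOLENCE_CATEGORIES",
    "DIAGNOSTIC_CATEGORIES",
    "TRAUMA_CATEGORIES",
    "CategoryMapper",
    "MappingError",
    "map_icd9_to_category",
    "category_id",
    "category_name",
]

#: Category names in id order: 9 violence, 13 named diagnostic groups,
#: other-diagnoses, missing-diagnosis, then the 5 trauma groups.
CATEGORIES: tuple[str, ...] = (
    "adult_maltreatment_unspecified",   # 995.80
    "adult_physical_abuse",             # 995.81
    "adult_emotional_abuse",            # 995.82
    "adult_sexual_abuse",               # 995.83
    "adult_neglect",                    # 995.84
    "other_adult_abuse",                # 995.85
    "history_physical_abuse",           # V15.41
    "history_emotional_abuse",          # V15.42
    "partner_abuse_counseling",         # V61.11
    "infectious",
    "psychoses",
    "alcohol_substance_abuse",
    "other_mental",
    "neurological",
    "circulatory",
    "genitourinary",
    "respiratory",
    "digestive",
    "symptoms_ill_defined",
    "pregnancy_related",
    "head_face",
    "traumatic_musculoskeletal",
    "other_diagnoses",
    "missing_diagnosis",
    "repeated_aggression",
    "trauma_work_school",
    "trauma_road",
    "trauma_home",
    "trauma_other",
)

N_CATEGORIES = len(CATEGORIES)
assert N_CATEGORIES == 29

VIOLENCE_CATEGORIES: tuple[str, ...] = CATEGORIES[:9]
DIAGNOSTIC_CATEGORIES: tuple[str, ...] = CATEGORIES[9:24]
TRAUMA_CATEGORIES: tuple[str, ...] = CATEGORIES[24:]

#: Exact-match violence diagnosis codes (the WVV proxy).
VIOLENCE_CODES: dict[str, str] = {
    "995.80": "adult_maltreatment_unspecified",
    "995.81": "adult_physical_abuse",
    "995.82": "adult_emotional_abuse",
    "995.83": "adult_sexual_abuse",
    "995.84": "adult_neglect",
    "995.85": "other_adult_abuse",
    "V15.41": "history_physical_abuse",
    "V15.42": "history_emotional_abuse",
    "V61.11": "partner_abuse_counseling",
}

_ID_OF = {name: i for i, name in enumerate(CATEGORIES)}

#: Trauma place field value → trauma category.
TRAUMA_PLACE_CATEGORY: dict[str, str] = {
    "work_school": "trauma_work_school",
    "road": "trauma_road",
    "home": "trauma_home",
    "other": "trauma_other",
}


class MappingError(ValueError):
    """Raised for a syntactically invalid ICD9-CM code."""


def category_id(name: str) -> int:
    return _ID_OF[name]


def category_name(cid: int) -> str:
    return CATEGORIES[cid]


_CODE_RE = re.compile(r"^([VE]?)(\d{1,3})(?:\.(\d{1,2}))?$")


def _normalize(code: str) -> str:
    """Normalize an ICD9-CM code to dotted form, e.g. '99581' -> '995.81'."""
    code = code.strip().upper().replace(" ", "")
    if not code:
        raise MappingError("empty ICD9-CM code")
    if "." not in code:
        # V codes carry 2 digits before the dot (V15.41), E codes 3 (E812.0),
        # plain numeric codes 3 (995.81).
        head = {"V": 3, "E": 4}.get(code[0], 3)
        if len(code) > head:
            code = code[:head] + "." + code[head:]
    if not _CODE_RE.match(code):
        raise MappingError(f"invalid ICD9-CM code: {code!r}")
    return code


def _numeric_value(code: str) -> float:
    """Numeric value of a dotted numeric code ('995.81' -> 995.81)."""
    return float(code)


@dataclass
class CategoryMapper:
    """Maps ICD9-CM codes to the 29 analysis categories.

    Violence codes are matched exactly against the nine listed codes; head and
    face diagnoses (identified by a configurable code list, independently of
    their traumatic origin) take precedence over the numeric chapter ranges;
    all remaining codes are assigned by range; anything unmatched falls back
    to ``other_diagnoses``.
    """

    ranges: list[tuple[float, float, str]]
    head_face_ranges: list[tuple[float, float]]
    head_face_codes: frozenset[str]

    @classmethod
    def from_config(cls, cfg: dict) -> "CategoryMapper":
        ranges = [
            (float(lo), float(hi), group)
            for group, pairs in cfg["groups"].items()
            for lo, hi in pairs
        ]
        hf = cfg.get("head_face", {})
        return cls(
            ranges=ranges,
            head_face_ranges=[(float(lo), float(hi)) for lo, hi in hf.get("ranges", [])],
            head_face_codes=frozenset(str(c) for c in hf.get("codes", [])),
        )

    @classmethod
    def default(cls) -> "CategoryMapper":
        text = resources.files("viosna.data").joinpath("icd9_groups.yaml").read_text()
        return cls.from_config(yaml.safe_load(text))

    def map_code(self, code: str, head_face_flag: bool = False) -> int:
        """Return the category id for one ICD9-CM code.

        Parameters
        ----------
        code : str
            ICD9-CM code, dotted or undotted ('995.81' or '99581').
        head_face_flag : bool
            External indication that the diagnosis involved head or face;
            forces the head/face category for non-violence codes.
        """
        norm = _normalize(code)
        if norm in VIOLENCE_CODES:
            return _ID_OF[VIOLENCE_CODES[norm]]
        if head_face_flag:
            return _ID_OF["head_face"]
        if norm[0] in "VE":
            return _ID_OF["other_diagnoses"]
        value = _numeric_value(norm)
        if norm in self.head_face_codes or any(
            lo <= value <= hi for lo, hi in self.head_face_ranges
        ):
            return _ID_OF["head_face"]
        for lo, hi, group in self.ranges:
            if lo <= value <= hi:
                return _ID_OF[group]
        return _ID_OF["other_diagnoses"]


_DEFAULT_MAPPER: CategoryMapper | None = None


def default_mapper() -> CategoryMapper:
    global _DEFAULT_MAPPER
    if _DEFAULT_MAPPER is None:
        _DEFAULT_MAPPER = CategoryMapper.default()
    return _DEFAULT_MAPPER


def map_icd9_to_category(code: str, head_face_flag: bool = False) -> int:
    """Map one ICD9-CM code to its category id with the default group table."""
    return default_mapper().map_code(code, head_face_flag)
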