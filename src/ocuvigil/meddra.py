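"""MedDRA-style standardization of verbatim event terms.

MedDRA itself is a licensed dictionary and cannot be redistributed, so the
module is mapping-table driven: a :class:`TermMap` holds verbatim→PT,
PT→SOC and PT→ocular-category assignments, loadable from CSV for users
with a licensed dictionary.  A bundled fixture covers the ocular Preferred
Terms analysed in this package plus common non-ocular terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, StandardizationError

OCULAR_SOC = "Eye disorders"

#: ocular PT categories used for grouped reporting
GROUPS = (
    "conjunctival",
    "corneal",
    "optic-nerve",
    "retinal",
    "eyelid",
    "ocular-motility",
    "ocular-infection",
    "other",
)

# (pt, soc, group) — group empty for non-ocular terms
_FIXTURE_TERMS: tuple[tuple[str, str, str], ...] = (
    ("Eye allergy", OCULAR_SOC, "conjunctival"),
    ("Eye discharge", OCULAR_SOC, "conjunctival"),
    ("Ocular hyperaemia", OCULAR_SOC, "conjunctival"),
    ("Conjunctival haemorrhage", OCULAR_SOC, "conjunctival"),
    ("Keratitis", OCULAR_SOC, "corneal"),
    ("Ulcerative keratitis", OCULAR_SOC, "corneal"),
    ("Cornea verticillata", OCULAR_SOC, "corneal"),
    ("Optic nerve disorder", OCULAR_SOC, "optic-nerve"),
    ("Optic ischaemic neuropathy", OCULAR_SOC, "optic-nerve"),
    ("Papilloedema", OCULAR_SOC, "optic-nerve"),
    ("Visual field defect", OCULAR_SOC, "optic-nerve"),
    ("Diabetic retinopathy", OCULAR_SOC, "retinal"),
    ("Retinal haemorrhage", OCULAR_SOC, "retinal"),
    ("Retinal vein occlusion", OCULAR_SOC, "retinal"),
    ("Macular oedema", OCULAR_SOC, "retinal"),
    ("Macular degeneration", OCULAR_SOC, "retinal"),
    ("Maculopathy", OCULAR_SOC, "retinal"),
    ("Retinal detachment", OCULAR_SOC, "retinal"),
    ("Vitreous floaters", OCULAR_SOC, "retinal"),
    ("Vitreous detachment", OCULAR_SOC, "retinal"),
    ("Eyelid disorder", OCULAR_SOC, "eyelid"),
    ("Swelling of eyelid", OCULAR_SOC, "eyelid"),
    ("Eyelids pruritus", OCULAR_SOC, "eyelid"),
    ("Eyelid oedema", OCULAR_SOC, "eyelid"),
    ("Eyelid margin crusting", OCULAR_SOC, "eyelid"),
    ("Eyelid ptosis", OCULAR_SOC, "eyelid"),
    ("Dark circles under eyes", OCULAR_SOC, "eyelid"),
    ("Erythema of eyelid", OCULAR_SOC, "eyelid"),
    ("Blepharitis", OCULAR_SOC, "eyelid"),
    ("Strabismus", OCULAR_SOC, "ocular-motility"),
    ("Eye movement disorder", OCULAR_SOC, "ocular-motility"),
    ("Diplopia", OCULAR_SOC, "ocular-motility"),
    ("Eye infection", OCULAR_SOC, "ocular-infection"),
    ("Conjunctivitis", OCULAR_SOC, "ocular-infection"),
    ("Hordeolum", OCULAR_SOC, "ocular-infection"),
    ("Eye haemorrhage", OCULAR_SOC, "other"),
    ("Uveitis", OCULAR_SOC, "other"),
    ("Eye inflammation", OCULAR_SOC, "other"),
    ("Eye pruritus", OCULAR_SOC, "other"),
    ("Visual impairment", OCULAR_SOC, "other"),
    ("Vision blurred", OCULAR_SOC, "other"),
    ("Lacrimation increased", OCULAR_SOC, "other"),
    ("Cataract", OCULAR_SOC, "other"),
    ("Dry eye", OCULAR_SOC, "other"),
    ("Eye disorder", OCULAR_SOC, "other"),
    ("Blindness", OCULAR_SOC, "other"),
    ("Eye pain", OCULAR_SOC, "other"),
    ("Eye swelling", OCULAR_SOC, "other"),
    ("Myopia", OCULAR_SOC, "other"),
    ("Glaucoma", OCULAR_SOC, "other"),
    ("Nausea", "Gastrointestinal disorders", ""),
    ("Vomiting", "Gastrointestinal disorders", ""),
    ("Diarrhoea", "Gastrointestinal disorders", ""),
    ("Neutropenia", "Blood and lymphatic system disorders", ""),
    ("Leukopenia", "Blood and lymphatic system disorders", ""),
    ("Anaemia", "Blood and lymphatic system disorders", ""),
    ("Fatigue", "General disorders and administration site conditions", ""),
    ("Pyrexia", "General disorders and administration site conditions", ""),
    ("Drug ineffective", "General disorders and administration site conditions", ""),
    ("Headache", "Nervous system disorders", ""),
    ("Dizziness", "Nervous system disorders", ""),
    ("Alopecia", "Skin and subcutaneous tissue disorders", ""),
    ("Rash", "Skin and subcutaneous tissue disorders", ""),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", ""),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", ""),
    ("Hot flush", "Vascular disorders", ""),
)

# extra verbatim spellings beyond the PT's own name
_FIXTURE_VERBATIMS: tuple[tuple[str, str], ...] = (
    ("DRY EYES", "Dry eye"),
    ("BLURRY VISION", "Vision blurred"),
    ("BLURRED VISION", "Vision blurred"),
    ("LOSS OF VISION", "Blindness"),
    ("WATERY EYES", "Lacrimation increased"),
    ("EPIPHORA", "Lacrimation increased"),
    ("EYE ITCHING", "Eye pruritus"),
    ("RED EYE", "Ocular hyperaemia"),
    ("DOUBLE VISION", "Diplopia"),
    ("VORTEX KERATOPATHY", "Cornea verticillata"),
)


@dataclass
class TermMap:
    """Verbatim→PT, PT→SOC and PT→ocular-group mappings (case-insensitive)."""

    pt_of_verbatim: dict[str, str]
    soc_of_pt: dict[str, str]
    group_of_pt: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pt_of_verbatim = {
            k.strip().upper(): v for k, v in self.pt_of_verbatim.items()
        }
        for pt, grp in self.group_of_pt.items():
            if grp and grp not in GROUPS:
                raise ConfigurationError(
                    f"term map: unknown ocular group {grp!r} for PT {pt!r}"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TermMap":
        """Build from a table with columns verbatim, pt, soc[, group]."""
        soc = frame.drop_duplicates("pt").set_index("pt")["soc"]
        multi = frame.groupby("pt")["soc"].nunique()
        bad = multi[multi > 1]
        if len(bad):
            raise ConfigurationError(
                f"term map: PTs mapped to multiple SOCs: {list(bad.index)}"
            )
        group = (
            frame.drop_duplicates("pt").set_index("pt")["group"]
            if "group" in frame.columns
            else pd.Series(dtype=object)
        )
        return cls(
            pt_of_verbatim=dict(zip(frame["verbatim"], frame["pt"])),
            soc_of_pt=soc.to_dict(),
            group_of_pt=group.fillna("").to_dict(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TermMap":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "verbatim": verbatim,
                "pt": pt,
                "soc": self.soc_of_pt.get(pt, ""),
                "group": self.group_of_pt.get(pt, ""),
            }
            for verbatim, pt in sorted(self.pt_of_verbatim.items())
        ]
        return pd.DataFrame(rows, columns=["verbatim", "pt", "soc", "group"])

    def ocular_pts(self) -> set[str]:
        return {pt for pt, soc in self.soc_of_pt.items() if soc == OCULAR_SOC}


def default_term_map() -> TermMap:
    """The bundled fixture map (ocular PTs with categories + common terms)."""
    pt_of_verbatim = {pt.upper(): pt for pt, _, _ in _FIXTURE_TERMS}
    pt_of_verbatim.update({v.upper(): pt for v, pt in _FIXTURE_VERBATIMS})
    return TermMap(
        pt_of_verbatim=pt_of_verbatim,
        soc_of_pt={pt: soc for pt, soc, _ in _FIXTURE_TERMS},
        group_of_pt={pt: grp for pt, soc, grp in _FIXTURE_TERMS if grp},
    )


def standardize_events(
    events: pd.DataFrame,
    term_map: TermMap,
    unknown_policy: str = "passthrough",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map verbatim ``pt`` strings to standardized PT / SOC / group.

    ``unknown_policy`` is one of ``passthrough`` (keep the verbatim as the
    PT, SOC empty, logged — the default), ``drop`` (remove those rows) or
    ``error``.  Returns the standardized events and the unmapped-term
    report (term, count).
    """
    if unknown_policy not in {"passthrough", "drop", "error"}:
        raise ConfigurationError(f"unknown policy {unknown_policy!r}")
    out = events.copy()
    verbatim = out["pt"].astype(str).str.strip()
    key = verbatim.str.upper()
    mapped = key.map(term_map.pt_of_verbatim)
    unknown = mapped.isna()

    unmapped = (
        verbatim[unknown].value_counts().rename_axis("term").reset_index(name="count")
    )
    if unknown.any() and unknown_policy == "error":
        raise StandardizationError(
            f"unmapped verbatim terms: {sorted(set(verbatim[unknown]))[:20]}"
        )
    out["pt"] = mapped.fillna(verbatim)
    out["soc"] = out["pt"].map(term_map.soc_of_pt).fillna("")
    out["group"] = out["pt"].map(term_map.group_of_pt).fillna("")
    if unknown_policy == "drop":
        out = out[~unknown]
    return out, unmapped
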