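"""Amino-acid registry and isotope classification scheme.

Two orthogonal binnings drive every downstream analysis:

* **Carbon** — *essential* amino acids, whose carbon skeletons animals
  cannot synthesize de novo and which therefore pass from diet to
  consumer with little isotope fractionation, versus *nonessential*
  amino acids synthesized from cellular carbon pools.
* **Nitrogen** — *trophic* amino acids, which undergo extensive
  transamination/deamination and become enriched in 15N with each
  trophic transfer, versus *source* amino acids, which retain the
  baseline nitrogen isotope value of the food web.  Amino acids with
  limited or source-like behaviour (Gly, Ser, Thr, Tyr, Arg) are binned
  as source.

Glutamic acid and glutamine are reported jointly as ``Glx`` because acid
hydrolysis of tissue protein converts Gln to Glu; separate ``Gln``
records are rejected rather than silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "AminoAcid",
    "AminoAcidRegistry",
    "RegistryError",
    "DEFAULT_REGISTRY",
    "classify_amino_acid",
    "MEASURED_13",
    "EAA6_PANEL",
    "EAA5_PANEL",
    "SUMV_TROPHIC_SET",
    "WEIGHTED_MEAN_TROPHIC_SET",
    "WEIGHTED_MEAN_SOURCE_SET",
]

CARBON_CLASSES = ("essential", "nonessential")
NITROGEN_CLASSES = ("trophic", "source")


class RegistryError(KeyError):
    """Unknown or unclassifiable amino-acid code."""


@dataclass(frozen=True)
class AminoAcid:
    """A registry member with its carbon and nitrogen classifications."""

    code: str
    full_name: str
    carbon_class: str
    nitrogen_class: str

    def __post_init__(self) -> None:
        if self.carbon_class not in CARBON_CLASSES:
            raise ValueError(f"invalid carbon_class {self.carbon_class!r} for {self.code}")
        if self.nitrogen_class not in NITROGEN_CLASSES:
            raise ValueError(f"invalid nitrogen_class {self.nitrogen_class!r} for {self.code}")


# Codes that alias onto a canonical registry code after normalization.
_ALIASES = {"Glu": "Glx"}
# Codes rejected with an explanation instead of a generic unknown-code error.
_REJECTED = {
    "Gln": "glutamine is destroyed by acid hydrolysis; report the combined pool as Glx",
}


class AminoAcidRegistry:
    """Closed, user-extensible vocabulary of amino-acid codes.

    Classification is a total function: every member carries both a
    carbon and a nitrogen class, so a registry can never hold an
    unclassified amino acid.
    """

    def __init__(self, members: Iterable[AminoAcid]):
        self._members: dict[str, AminoAcid] = {}
        for m in members:
            if m.code in self._members:
                raise ValueError(f"duplicate registry code {m.code!r}")
            self._members[m.code] = m

    # -- lookup ---------------------------------------------------------
    def normalize(self, code: str) -> str:
        """Return the canonical code for ``code`` (case-insensitive, Glu→Glx).

        Raises :class:`RegistryError` for unknown or rejected codes.
        """
        cand = str(code).strip()
        cand = cand[:1].upper() + cand[1:].lower() if cand else cand
        cand = _ALIASES.get(cand, cand)
        if cand in _REJECTED:
            raise RegistryError(f"amino acid code {code!r} rejected: {_REJECTED[cand]}")
        if cand not in self._members:
            raise RegistryError(f"unknown amino acid code {code!r}")
        return cand

    def __contains__(self, code: str) -> bool:
        try:
            self.normalize(code)
        except RegistryError:
            return False
        return True

    def __getitem__(self, code: str) -> AminoAcid:
        return self._members[self.normalize(code)]

    def __iter__(self):
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    @property
    def codes(self) -> list[str]:
        return list(self._members)

    def classify(self, code: str, axis: str) -> str:
        member = self[code]
        if axis == "carbon":
            return member.carbon_class
        if axis == "nitrogen":
            return member.nitrogen_class
        raise ValueError(f"axis must be 'carbon' or 'nitrogen', got {axis!r}")

    def members_of(self, axis: str, label: str) -> list[str]:
        """Codes whose classification on ``axis`` equals ``label``."""
        return [m.code for m in self if self.classify(m.code, axis) == label]

    # -- construction / serialization -----------------------------------
    def with_member(self, member: AminoAcid) -> "AminoAcidRegistry":
        """Return a new registry extended by ``member``."""
        return AminoAcidRegistry(list(self) + [member])

    def to_dict(self) -> dict[str, dict[str, str]]:
        return {
            m.code: {
                "full_name": m.full_name,
                "carbon_class": m.carbon_class,
                "nitrogen_class": m.nitrogen_class,
            }
            for m in self
        }

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Mapping[str, str]]) -> "AminoAcidRegistry":
        return cls(
            AminoAcid(
                code=code,
                full_name=spec.get("full_name", code),
                carbon_class=spec["carbon_class"],
                nitrogen_class=spec["nitrogen_class"],
            )
            for code, spec in mapping.items()
        )


def _default_members() -> list[AminoAcid]:
    e, n = "essential", "nonessential"
    t, s = "trophic", "source"
    return [
        AminoAcid("Ala", "alanine", n, t),
        AminoAcid("Arg", "arginine", n, s),
        AminoAcid("Asp", "aspartic acid", n, t),
        AminoAcid("Glx", "glutamic acid + glutamine", n, t),
        AminoAcid("Gly", "glycine", n, s),
        AminoAcid("Ile", "isoleucine", e, t),
        AminoAcid("Leu", "leucine", e, t),
        AminoAcid("Lys", "lysine", e, s),
        AminoAcid("Met", "methionine", e, s),
        AminoAcid("Phe", "phenylalanine", e, s),
        AminoAcid("Pro", "proline", n, t),
        AminoAcid("Ser", "serine", n, s),
        AminoAcid("Thr", "threonine", e, s),
        AminoAcid("Tyr", "tyrosine", n, s),
        AminoAcid("Val", "valine", e, t),
    ]


DEFAULT_REGISTRY = AminoAcidRegistry(_default_members())

#: The 13 amino acids routinely resolved by GC-IRMS after TFA derivatization
#: (Arg and Met typically are not recovered or quantified reliably).
MEASURED_13 = [
    "Ala", "Asp", "Glx", "Gly", "Ile", "Leu", "Lys",
    "Phe", "Pro", "Ser", "Thr", "Tyr", "Val",
]

#: Six-essential-AA carbon fingerprint panel.
EAA6_PANEL = ["Ile", "Leu", "Lys", "Phe", "Thr", "Val"]
#: Five-AA panel for cross-study comparisons where lysine is unavailable.
EAA5_PANEL = ["Ile", "Leu", "Phe", "Thr", "Val"]
#: Trophic amino acids entering the sum-V resynthesis index.
SUMV_TROPHIC_SET = ["Ala", "Leu", "Pro", "Asp", "Glx"]
#: Trophic/source sets for the d15N-weighted-mean trophic proxy.
WEIGHTED_MEAN_TROPHIC_SET = ["Ala", "Leu", "Glx"]
WEIGHTED_MEAN_SOURCE_SET = ["Lys", "Phe"]


def classify_amino_acid(
    code: str, axis: str, registry: AminoAcidRegistry = DEFAULT_REGISTRY
) -> str:
    """Classify ``code`` on the ``carbon`` (essential/nonessential) or
    ``nitrogen`` (trophic/source) axis."""
    return registry.classify(code, axis)
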