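"""Domain types for the UvrA2 ATPase mechanism: rate constants, mechanism
variants and experimental conditions.

The UvrA2 dimer carries four ABC-type ATPase sites, two per monomer: a
high-affinity *distal* pair (nucleotide dissociation constant KD1 ~ 1 µM)
and a low-affinity *proximal* pair (KD2 ~ 350 µM).  The minimal mechanism
treats each pair as one lumped species.  The reaction chain is

    apo --k1·[ATP]/k_minus1--> distal-ATP  <==KD2==>  distal+proximal-ATP
        --k3--> distal-ADP·Pi --k4 (burst Pi)--> distal-ADP
        --k5a or k5b--> recycle

where k3 is the hydrolysis-limiting step, k4 the fast Pi-release step and
the k5 step (ADP release) limits steady-state turnover.  ``n_sites`` is the
fitted burst stoichiometry: Pi released rapidly per dimer per turnover.

Parameter presets carry the published best-fit values for the wild-type
enzyme and, for DNA-bound and mutant forms, rate sets that reproduce the
published turnover numbers (see docs/methods.md for how those were derived).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "RateParameterSet",
    "MechanismVariant",
    "ExperimentCondition",
    "VARIANTS",
    "PARAM_PRESETS",
    "variant_preset",
    "TWO_ACTIVE_SITES",
    "FOUR_ACTIVE_SITES",
]

TWO_ACTIVE_SITES = "two_active_sites"
FOUR_ACTIVE_SITES = "four_active_sites"

#: total composite ATPase sites on the dimer
TOTAL_SITES = 4

_REL_TOL_KD1 = 1e-9


@dataclass(frozen=True)
class RateParameterSet:
    """Rate and equilibrium constants of the lumped ATPase mechanism.

    Bimolecular constants (``k1``) are in M⁻¹ s⁻¹, first-order rates in s⁻¹
    and dissociation constants in µM.  ``KD1`` may be omitted, in which case
    it is derived as ``k_minus1 / k1``; if both are given they must agree.
    ``proximal_on_rate`` is the fixed proximal association rate used to
    realize the rapid-equilibrium KD2 step kinetically (M⁻¹ s⁻¹); it is not
    a fitted quantity and only needs to be fast enough to be non-limiting.
    """

    k1: float  # ATP association, distal sites (M^-1 s^-1)
    k_minus1: float  # ATP dissociation, distal sites (s^-1)
    KD2: float  # proximal ATP dissociation constant (uM)
    k3: float  # hydrolysis-limiting step (s^-1)
    k4: float  # Pi-release step (s^-1)
    k5a: float  # ADP release, two-active-site branch (s^-1)
    k5b: float  # turnover-limiting step, four-active-site branch (s^-1)
    n_sites: float  # burst stoichiometry (Pi per dimer per turnover)
    KD1: float | None = None  # distal dissociation constant (uM)
    proximal_on_rate: float = 1e6  # fixed proximal on-rate (M^-1 s^-1)

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "KD2", "k3", "k4", "k5a", "k5b",
                     "proximal_on_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if not (0 < self.n_sites <= 8):
            raise ValueError(f"n_sites must lie in (0, 8], got {self.n_sites}")
        if self.KD1 is None:
            object.__setattr__(self, "KD1", self.derived_kd1())
        else:
            derived = self.derived_kd1()
            if derived is not None and self.KD1 > 0:
                if abs(self.KD1 - derived) > _REL_TOL_KD1 * self.KD1:
                    raise ValueError(
                        f"KD1={self.KD1} inconsistent with k_minus1/k1={derived}"
                    )

    def derived_kd1(self) -> float | None:
        """KD1 in µM implied by ``k_minus1 / k1`` (None if k1 == 0)."""
        if self.k1 == 0:
            return None
        return self.k_minus1 / self.k1 * 1e6  # M -> uM

    def with_updates(self, **kwargs: float) -> "RateParameterSet":
        """Copy with selected constants replaced (KD1 re-derived unless given)."""
        if "KD1" not in kwargs and ("k1" in kwargs or "k_minus1" in kwargs):
            kwargs["KD1"] = None
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MechanismVariant:
    """Which site classes bind and hydrolyze ATP, and which recycling branch
    applies.

    ``branch`` selects how the dimer returns to the cycle after the burst:
    ``two_active_sites`` (only the burst pair cycles; recycle through a
    transiently empty burst-site state) or ``four_active_sites`` (the other
    pair also hydrolyzes once per turnover, collapsed into the single k5b
    step).  ``burst_present`` records whether the variant shows a fast Pi
    burst at all; binding-dead Walker A mutants do not.
    """

    name: str
    proximal_binds: bool = True
    distal_binds: bool = True
    proximal_hydrolyzes: bool = True
    distal_hydrolyzes: bool = True
    branch: str = FOUR_ACTIVE_SITES
    burst_present: bool = True

    def __post_init__(self) -> None:
        if self.branch not in (TWO_ACTIVE_SITES, FOUR_ACTIVE_SITES):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.proximal_hydrolyzes and not self.proximal_binds:
            raise ValueError(
                "proximal_hydrolyzes=True requires proximal_binds=True"
            )
        if self.distal_hydrolyzes and not self.distal_binds:
            raise ValueError("distal_hydrolyzes=True requires distal_binds=True")


@dataclass(frozen=True)
class ExperimentCondition:
    """Concentrations and context of one stopped-flow shot (all µM)."""

    enzyme_total: float = 0.0  # dimer
    atp_total: float = 0.0
    dna: str = "none"  # none | native | lesion
    dna_conc: float = 0.0
    chase: str = "none"  # none | ADP | ATP
    chase_conc: float = 0.0
    mant_conc: float = 0.0
    temperature_note: str = "40C"

    def __post_init__(self) -> None:
        for name in ("enzyme_total", "atp_total", "dna_conc", "chase_conc",
                     "mant_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dna not in ("none", "native", "lesion"):
            raise ValueError(f"unknown dna kind {self.dna!r}")
        if self.dna == "none" and self.dna_conc != 0:
            raise ValueError("dna='none' requires dna_conc=0")
        if self.chase not in ("none", "ADP", "ATP"):
            raise ValueError(f"unknown chase {self.chase!r}")


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

_WT = dict(k1=3e4, k_minus1=0.03, KD2=350.0, k4=19.0, k5a=0.44, k5b=0.18)

#: published best-fit wild-type (apo) parameter set
WILD_TYPE_BEST_FIT = RateParameterSet(k3=2.45, n_sites=1.9, **_WT)

VARIANTS: dict[str, MechanismVariant] = {
    "wild_type_apo": MechanismVariant("wild_type_apo"),
    "wild_type_native": MechanismVariant("wild_type_native"),
    # at a lesion the post-hydrolysis steps are fast; a step before/at
    # hydrolysis limits turnover, so no burst is observed
    "wild_type_lesion": MechanismVariant(
        "wild_type_lesion", branch=TWO_ACTIVE_SITES, burst_present=False
    ),
    # Walker A proximal: no proximal ATP binding -> no flux past distal binding
    "K37A": MechanismVariant(
        "K37A", proximal_binds=False, proximal_hydrolyzes=False,
        branch=TWO_ACTIVE_SITES, burst_present=False,
    ),
    # Walker A distal: no distal nucleotide binding at tested concentrations
    "K643A": MechanismVariant(
        "K643A", distal_binds=False, distal_hydrolyzes=False,
        branch=TWO_ACTIVE_SITES, burst_present=False,
    ),
    "K37A_K643A": MechanismVariant(
        "K37A_K643A", proximal_binds=False, distal_binds=False,
        proximal_hydrolyzes=False, distal_hydrolyzes=False,
        branch=TWO_ACTIVE_SITES, burst_present=False,
    ),
    # Walker B proximal: binds but cannot hydrolyze -> distal-only turnover
    "E512A": MechanismVariant(
        "E512A", proximal_hydrolyzes=False, branch=TWO_ACTIVE_SITES
    ),
    # Walker B distal: distal pair binds but cannot hydrolyze; the proximal
    # pair carries a slow, burst-free turnover (lag then linear)
    "E854A": MechanismVariant(
        "E854A", distal_hydrolyzes=False, branch=TWO_ACTIVE_SITES,
        burst_present=False,
    ),
}

#: generator parameter presets per (variant, dna) context; values either the
#: published global-fit sets or derived from published kcat (docs/methods.md)
PARAM_PRESETS: dict[str, RateParameterSet] = {
    "wild_type_apo": WILD_TYPE_BEST_FIT,
    # native-DNA global fit: k3=2.4, k4=30, k5=1, n=5.4
    "wild_type_native": RateParameterSet(
        k1=3e4, k_minus1=0.03, KD2=350.0, k3=2.4, k4=30.0,
        k5a=1.0, k5b=1.0, n_sites=5.4,
    ),
    # lesion: post-hydrolysis steps fast (ADP release 13 s^-1, the ATP-chase
    # dissociation rate); k3 chosen so the model kcat is 1.4 s^-1
    "wild_type_lesion": RateParameterSet(
        k1=3e4, k_minus1=0.03, KD2=350.0, k3=6.0, k4=30.0,
        k5a=13.0, k5b=13.0, n_sites=2.0,
    ),
    "K37A": WILD_TYPE_BEST_FIT,
    "K643A": WILD_TYPE_BEST_FIT,
    "K37A_K643A": WILD_TYPE_BEST_FIT,
    # proximal Walker B mutant, distal-pair-only cycling
    "E512A": RateParameterSet(
        k1=3e4, k_minus1=0.03, KD2=350.0, k3=2.0, k4=42.0,
        k5a=0.6, k5b=0.6, n_sites=1.3,
    ),
    # same mutant on native DNA: faster ADP release reproduces kcat = 0.6
    "E512A_native": RateParameterSet(
        k1=3e4, k_minus1=0.03, KD2=350.0, k3=2.0, k4=42.0,
        k5a=2.9, k5b=2.9, n_sites=1.3,
    ),
    # distal Walker B mutant: slow proximal-pair turnover, no burst
    "E854A": RateParameterSet(
        k1=3e4, k_minus1=0.03, KD2=350.0, k3=1.0, k4=30.0,
        k5a=5.0, k5b=5.0, n_sites=2.0,
    ),
}


def variant_preset(name: str) -> tuple[MechanismVariant, RateParameterSet]:
    """Look up the (variant, parameter) preset pair for ``name``."""
    key = name
    if key not in PARAM_PRESETS:
        raise KeyError(
            f"unknown variant {name!r}; valid presets: "
            + ", ".join(sorted(PARAM_PRESETS))
        )
    variant = VARIANTS.get(key)
    if variant is None:  # e.g. E512A_native -> E512A topology
        variant = VARIANTS[key.split("_")[0]]
    return variant, PARAM_PRESETS[key]
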