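"""Kinetic parameter set of the combined model.

The default parameterization (103 kinetic rate constants, shipped as
``data/default_parameters.json``) was calibrated so that one pass through
the limit cycle reproduces the programmed expression features of the K562
profiles: no detectable cyclin A until ~21% of the cycle, an earlier and
more strongly convex cyclin B rise, a shared rapid G2 rise of both mitotic
cyclins, abrupt activation of CycB:Cdk1 in the final few percent of the
cycle, and cyclin A degradation preceding cyclin B degradation at mitosis.

Rate constants are expressed per unit cycle time (fraction of Tc);
concentrations are in arbitrary units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "N_PARAMS",
    "ParameterSet",
    "UnknownParameterError",
    "default_parameters",
]

#: the 103 kinetic rate constants, grouped by mechanism.  Order is the
#: storage order of :meth:`ParameterSet.to_array`.
PARAM_NAMES: tuple[str, ...] = (
    # early/delayed response genes (growth signalling)
    "k_serg", "k_derg",
    "k_sdrg", "k_sdrg_drg", "J_drg", "k_ddrg",
    # cyclin D synthesis/turnover and CKI binding
    "k_sd", "J_sd", "k_dd", "k_asd", "k_did", "k_dd_k",
    # Rb phosphorylation cycle
    "k_prb_d", "k_prb_dk", "k_prb_e", "k_prb_a", "k_dprb",
    "k_prb2_e", "k_prb2_a", "k_dprb2",
    # E2F:Rb binding and turnover of sequestered E2F
    "k_as_fe", "k_di_fe", "k_de2f_rb",
    # E2F synthesis (autocatalytic), phosphorylation and degradation
    "k_se2f_basal", "k_se2f", "J_se2f",
    "k_pe2f_a", "k_pe2f_b", "k_dpe2f",
    "k_de2f", "k_de2f_p", "k_de2f_20", "k_de2f_h1",
    # cyclin E
    "k_se_basal", "k_se", "k_de", "k_de_a", "k_ase", "k_die", "k_de_k",
    # CKI (Kip1)
    "k_ski", "k_dki", "k_dki_d", "k_dki_e", "k_dki_a", "k_dki_b",
    # cyclin A (both Cdk pools)
    "k_sa_basal", "k_sa_e2f", "k_sa_ab",
    "k_da", "k_da_20", "k_da_h1", "k_asa", "k_dia",
    # cyclin B synthesis/degradation
    "k_sb_basal", "k_sb_e2f", "k_sb_ab", "k_sb_b",
    "k_db", "k_db_20", "k_db_h1",
    # Wee1/Cdc25 action on CycB:Cdk1
    "k_wee_basal", "k_wee_b", "k_25_basal", "k_25_b",
    # Wee1 activity switch (inactivated by cyclin A/Cdk)
    "k_aw", "J_aw", "k_iw_a", "k_iw_b", "J_iw",
    # Cdc25 activity switch (activated by active CycB:Cdk1)
    "k_a25_b", "k_a25_a", "J_a25", "k_i25", "J_i25",
    # Cdh1 activity switch
    "k_ah1", "k_ah1_20", "J_ah1",
    "k_ih1_basal", "k_ih1_d", "k_ih1_e", "k_ih1_a", "k_ih1_b", "J_ih1",
    # Cdc20 synthesis, activation and turnover
    "k_s20_basal", "k_s20_a", "k_s20_b", "k_d20",
    "k_a20", "J_a20", "k_i20", "J_i20", "k_d20a",
    # intermediary enzyme (APC/C phosphorylation delay)
    "k_aie", "J_aie", "k_iie", "J_iie",
    # G2 transcription factor TFAB
    "k_atf", "J_atf", "k_itf", "k_itf_b", "k_itf_20", "J_itf",
)

N_PARAMS: int = len(PARAM_NAMES)
PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}


class UnknownParameterError(KeyError):
    """Raised when an override or file names a parameter that does not exist."""


@dataclass(frozen=True)
class ParameterSet:
    """The 103 named rate constants plus structural and solver options.

    Parameters
    ----------
    constants
        Mapping name -> nonnegative rate constant; must contain exactly
        the names in :data:`PARAM_NAMES`.
    cyclinA_cdk2_synthesis_fraction
        Fraction of cyclin A synthesis routed to the CycA:Cdk2 pool
        (the remainder forms CycA:Cdk1); encodes the preferential
        binding of cyclin A to Cdk2.
    rtol, atol, max_step
        Stiff-solver options used by :func:`cdkcycle.model.simulate`.
    """

    constants: dict[str, float]
    cyclinA_cdk2_synthesis_fraction: float = 0.8
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        extra = set(self.constants) - set(PARAM_NAMES)
        missing = set(PARAM_NAMES) - set(self.constants)
        if extra or missing:
            raise UnknownParameterError(
                f"parameter set must contain exactly the {N_PARAMS} model "
                f"constants; missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, value in self.constants.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name!r} must be finite and >= 0, got {value!r}")
        f = self.cyclinA_cdk2_synthesis_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"cyclinA_cdk2_synthesis_fraction must lie in [0, 1], got {f}")

    def __getitem__(self, name: str) -> float:
        try:
            return self.constants[name]
        except KeyError:
            raise UnknownParameterError(name) from None

    def with_overrides(self, overrides: dict[str, float]) -> "ParameterSet":
        """Return a copy with the named constants replaced."""
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise UnknownParameterError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        new = dict(self.constants)
        new.update({k: float(v) for k, v in overrides.items()})
        return replace(self, constants=new)

    def to_array(self) -> np.ndarray:
        """Rate constants in :data:`PARAM_NAMES` order, with the cyclin A
        synthesis split appended as the final element (length 104)."""
        arr = np.empty(N_PARAMS + 1)
        for i, n in enumerate(PARAM_NAMES):
            arr[i] = self.constants[n]
        arr[N_PARAMS] = self.cyclinA_cdk2_synthesis_fraction
        return arr

    def to_dict(self) -> dict:
        return {
            "constants": dict(self.constants),
            "cyclinA_cdk2_synthesis_fraction": self.cyclinA_cdk2_synthesis_fraction,
            "solver": {"rtol": self.rtol, "atol": self.atol},
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ParameterSet":
        solver = payload.get("solver", {})
        return cls(
            constants={k: float(v) for k, v in payload["constants"].items()},
            cyclinA_cdk2_synthesis_fraction=float(
                payload.get("cyclinA_cdk2_synthesis_fraction", 0.8)
            ),
            rtol=float(solver.get("rtol", 1e-8)),
            atol=float(solver.get("atol", 1e-10)),
            meta=dict(payload.get("meta", {})),
        )


def _load_packaged(name: str) -> dict:
    with resources.files("cdkcycle.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def default_parameters(overrides: dict[str, float] | None = None) -> ParameterSet:
    """The packaged default parameterization, optionally with overrides.

    The packaged defaults are never mutated; each call returns a fresh
    :class:`ParameterSet`.
    """
    ps = ParameterSet.from_dict(_load_packaged("default_parameters.json"))
    if overrides:
        ps = ps.with_overrides(overrides)
    return ps


def default_initial_state() -> np.ndarray:
    """Packaged start-of-cycle state (just after a division event)."""
    from .species import SPECIES_NAMES

    payload = _load_packaged("initial_state.json")
    return np.array([payload[n] for n in SPECIES_NAMES], dtype=float)
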