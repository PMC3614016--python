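"""Microscopic rate constants of the clamp loading/unloading/capture cycle.

Concentrations are in nM, time in seconds throughout the package.  The
default values are the experimentally determined constants for the human
RFC / PCNA / pol-delta system:

* ``k_conf`` — first-order conformational step after the loader·clamp·DNA
  encounter complex forms; produces the observed FRET rise (6.4 s^-1).
* ``k_close`` — hydrolysis-coupled ring closure and release of the clamp
  onto DNA; produces the observed FRET decrease (1.4 s^-1).
* ``k_off_fast`` / ``k_off_slow`` — biphasic dissociation of the resident
  loader from DNA, which carries the clamp back into solution (0.40 /
  0.039 s^-1).  ``p_fast`` is the fraction of loader in the
  fast-dissociating form (0.83).
* ``k_capture`` — bimolecular capture of a released (ring-closed) clamp by
  the polymerase, forming the holoenzyme and occluding the unloading
  activity.  Default is fast and non-limiting.
* ``K_d_rfc_pcna`` — loader·ATP / clamp dissociation constant (~0.2 nM),
  used for the instantaneous solution-phase partitioning of loader among
  clamp pools.
* ``k_slide`` — escape of a released clamp over an unblocked DNA end
  (0 when the end is blocked).
* ``k_subunit_exchange`` — spontaneous disassembly of the clamp trimer on
  DNA (6.3e-3 s^-1 when enabled; 0 by default since it is never observed
  in the presence of ATP).
* ``hydrolysis_enabled`` — False models ATPgammaS: ring closure and the
  hydrolysis-dependent fast dissociation are switched off.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Effective bimolecular rate used when DNA binding is declared
#: "instantaneous" (nM^-1 s^-1).  At working concentrations (>= 10 nM free
#: DNA) this gives pseudo-first-order binding >= 1e3 s^-1, far above
#: k_conf, so the observed rise rate equals k_conf.
INSTANTANEOUS_K_ON = 100.0


class RateParameters(BaseModel):
    """Rate constants and population fractions of the assembly mechanism."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    k_conf: float = Field(default=6.4, ge=0.0)
    k_close: float = Field(default=1.4, ge=0.0)
    p_fast: float = Field(default=0.83, ge=0.0, le=1.0)
    k_off_fast: float = Field(default=0.40, ge=0.0)
    k_off_slow: float = Field(default=0.039, ge=0.0)
    k_capture: float = Field(default=1.0, ge=0.0)
    k_on_dna: float | str = "instantaneous"
    K_d_rfc_pcna: float = Field(default=0.2, gt=0.0)
    k_slide: float = Field(default=0.0, ge=0.0)
    k_subunit_exchange: float = Field(default=0.0, ge=0.0)
    hydrolysis_enabled: bool = True

    @model_validator(mode="after")
    def _check_k_on(self) -> "RateParameters":
        if isinstance(self.k_on_dna, str):
            if self.k_on_dna != "instantaneous":
                raise ValueError(
                    "k_on_dna must be a non-negative rate or 'instantaneous'"
                )
        elif self.k_on_dna < 0:
            raise ValueError("k_on_dna must be >= 0")
        return self

    @property
    def effective_k_on(self) -> float:
        if self.k_on_dna == "instantaneous":
            return INSTANTANEOUS_K_ON
        return float(self.k_on_dna)

    @property
    def effective_k_close(self) -> float:
        """Ring closure requires ATP hydrolysis; zero under ATPgammaS."""
        return self.k_close if self.hydrolysis_enabled else 0.0

    @property
    def effective_k_off_fast(self) -> float:
        """The fast dissociation phase is hydrolysis-dependent."""
        return self.k_off_fast if self.hydrolysis_enabled else 0.0
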