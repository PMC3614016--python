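"""Reaction network for the stepwise clamp loading / unloading / capture cycle.

The network encodes, for each clamp label status (acceptor-labeled or
unlabeled) and each loader population (fast- or slow-dissociating), the
chain::

    loader·clamp (solution) --bind DNA--> open complex
        --k_conf--> notched (high-FRET) complex
        --k_close--> released complex (ring closed, loader resident)
        --k_off(pop)--> loader + clamp jointly back to solution

with optional branches: polymerase capture of a released clamp
(holoenzyme, no outgoing unloading reaction), slide-off over an unblocked
DNA end, and spontaneous clamp-subunit exchange.

Two non-elementary conventions, both justified by the measured constants:

* DNA binding of the solution loader·clamp complex is "instantaneous"
  (not observed at any loader concentration); it is realized as a fast
  bimolecular step whose rate law partitions the solution loader among
  clamp pools in proportion to their concentrations — the K_d << [clamp]
  limit of the loader/clamp binding equilibrium.
* Unloading returns loader and clamp to solution in a single joint step:
  the process is rate-limited entirely by loader dissociation from DNA,
  and no clamp is left behind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .params import RateParameters

DESIGN_KINDS = frozenset(
    {"loading", "pulse_chase", "chase_control", "unload_trap", "reload",
     "reload_poldelta", "titration_member"}
)

#: Design kinds whose mixes contain polymerase.
_POLDELTA_KINDS = frozenset({"reload_poldelta", "titration_member"})

LABELS = ("lab", "unl")
POPS = ("fast", "slow")

# Default per-stage FRET weights for complexes containing a labeled clamp
# on DNA.  The open encounter complex transfers at half efficiency, the
# notched (spiral) complex is the high-FRET state, and ring-closed states
# retain intermediate proximity.
DEFAULT_FRET_WEIGHTS = {
    "open": 0.5,
    "notched": 1.0,
    "released": 0.6,
    "holoenzyme": 0.6,
}


@dataclass(frozen=True)
class Species:
    name: str
    clamp_label: str       # "labeled" | "unlabeled" | "none"
    location: str          # "solution" | "dna" | "sink"
    stage: str             # free | open | notched | released | holoenzyme | loader | escaped | exchanged


@dataclass(frozen=True)
class Reaction:
    """One channel of the network.

    ``kind`` is "mass_action" (molecularity 1 or 2, elementary rate law)
    or "loading" (the instantaneous-partitioning DNA-binding step, whose
    rate is k_on * [DNA] * [loader_sol] * [clamp_L] / (sum clamp + K_d)).
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float
    kind: str = "mass_action"
    clamp_pool: int = -1          # loading only: which clamp pool is consumed
    tag: str = "core"             # core | capture | slide | sx

    @property
    def molecularity(self) -> int:
        return len(self.reactants)


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    fret_coefficients: np.ndarray
    clamp_pool_indices: tuple[int, ...]   # solution clamp pools (for partitioning)
    k_d_partition: float
    conservation: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def index(self, name: str) -> int:
        return self._index_map()[name]

    def _index_map(self) -> dict[str, int]:
        if not hasattr(self, "_imap"):
            self._imap = {s.name: i for i, s in enumerate(self.species)}
        return self._imap

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self, concentrations: dict[str, float]) -> np.ndarray:
        """Build a state vector from a name -> nM mapping (unknown names error)."""
        y0 = np.zeros(self.n_species)
        imap = self._index_map()
        for name, conc in concentrations.items():
            if name not in imap:
                raise KeyError(f"unknown species {name!r}")
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}")
            y0[imap[name]] = conc
        return y0

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dydt = np.zeros_like(y)
        pools = self.clamp_pool_indices
        c_tot = sum(max(y[i], 0.0) for i in pools)
        denom = c_tot + self.k_d_partition
        for rx in self.reactions:
            if rx.kind == "loading":
                dna, loader = rx.reactants
                flux = (
                    rx.rate
                    * max(y[dna], 0.0)
                    * max(y[loader], 0.0)
                    * max(y[rx.clamp_pool], 0.0)
                    / denom
                )
                dydt[dna] -= flux
                dydt[loader] -= flux
                dydt[rx.clamp_pool] -= flux
            else:
                flux = rx.rate
                for i in rx.reactants:
                    flux *= max(y[i], 0.0)
                for i in rx.reactants:
                    dydt[i] -= flux
            for i in rx.products:
                dydt[i] += flux
        return dydt

    def without_leaks(self) -> "ReactionNetwork":
        """A copy with the slow leak channels (slide-off, subunit
        exchange) switched off; used to pre-equilibrate pre-assembled
        complexes, whose defining endpoint is the loaded state rather
        than the fully disassembled one the leaks drain toward."""
        from dataclasses import replace

        reactions = [
            replace(r, rate=0.0) if r.tag in ("slide", "sx") else r
            for r in self.reactions
        ]
        return ReactionNetwork(
            species=self.species,
            reactions=reactions,
            fret_coefficients=self.fret_coefficients,
            clamp_pool_indices=self.clamp_pool_indices,
            k_d_partition=self.k_d_partition,
            conservation=self.conservation,
        )

    def to_dict(self) -> dict:
        return {
            "species": [vars(s) for s in self.species],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "rate": r.rate,
                    "kind": r.kind,
                    "molecularity": r.molecularity,
                }
                for r in self.reactions
            ],
            "fret_coefficients": self.fret_coefficients.tolist(),
            "k_d_partition": self.k_d_partition,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_network(
    params: RateParameters,
    design_kind: str,
    end_blocked: bool = True,
    fret_weights: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Assemble the reaction network for one experimental design.

    The polymerase-capture branch is present iff the design includes
    polymerase; a slide-off sink exists iff ``end_blocked`` is False; a
    subunit-exchange sink exists iff ``params.k_subunit_exchange > 0``.
    The two loader populations (fractions ``p_fast`` / ``1 - p_fast``)
    are pre-existing forms, each keeping its dissociation rate through
    the whole cycle; this is what makes the biphasic 83/17 amplitude
    split hold both for a single turnover and at loading equilibrium.
    """
    if design_kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design kind {design_kind!r}")
    weights = dict(DEFAULT_FRET_WEIGHTS)
    if fret_weights:
        weights.update(fret_weights)

    with_poldelta = design_kind in _POLDELTA_KINDS
    with_slide = not end_blocked and params.k_slide > 0
    with_sx = params.k_subunit_exchange > 0

    species: list[Species] = []

    def add(name, clamp_label, location, stage) -> int:
        species.append(Species(name, clamp_label, location, stage))
        return len(species) - 1

    i_dna = add("dna", "none", "solution", "free")
    i_rfc_sol = {p: add(f"rfc_{p}_sol", "none", "solution", "loader") for p in POPS}
    i_clamp = {
        "lab": add("pcna_lab_sol", "labeled", "solution", "free"),
        "unl": add("pcna_unl_sol", "unlabeled", "solution", "free"),
    }
    i_poldelta = add("poldelta_sol", "none", "solution", "free") if with_poldelta else -1

    full = {"lab": "labeled", "unl": "unlabeled"}
    i_open, i_notch, i_rel = {}, {}, {}
    for p in POPS:
        for lab in LABELS:
            i_open[p, lab] = add(f"open_{p}_{lab}", full[lab], "dna", "open")
            i_notch[p, lab] = add(f"notched_{p}_{lab}", full[lab], "dna", "notched")
            i_rel[p, lab] = add(f"released_{p}_{lab}", full[lab], "dna", "released")

    i_holo = {}
    i_rfc_post = {}
    if with_poldelta:
        for lab in LABELS:
            i_holo[lab] = add(f"holo_{lab}", full[lab], "dna", "holoenzyme")
        for p in POPS:
            i_rfc_post[p] = add(f"rfc_{p}_post", "none", "dna", "loader")

    i_rfc_vac = {}
    if with_slide or with_sx:
        for p in POPS:
            i_rfc_vac[p] = add(f"rfc_{p}_vacated", "none", "dna", "loader")
    i_escaped = {}
    if with_slide:
        for lab in LABELS:
            i_escaped[lab] = add(f"escaped_{lab}", full[lab], "sink", "escaped")
    i_exchanged = {}
    if with_sx:
        for lab in LABELS:
            i_exchanged[lab] = add(f"exchanged_{lab}", full[lab], "sink", "exchanged")

    k_off = {"fast": params.effective_k_off_fast, "slow": params.k_off_slow}
    k_on = params.effective_k_on

    reactions: list[Reaction] = []
    for p in POPS:
        for lab in LABELS:
            # DNA binding with instantaneous solution partitioning
            reactions.append(
                Reaction(
                    reactants=(i_dna, i_rfc_sol[p]),
                    products=(i_open[p, lab],),
                    rate=k_on,
                    kind="loading",
                    clamp_pool=i_clamp[lab],
                )
            )
            reactions.append(  # conformational step -> high-FRET notched state
                Reaction((i_open[p, lab],), (i_notch[p, lab],), params.k_conf)
            )
            reactions.append(  # hydrolysis-coupled closure/release
                Reaction((i_notch[p, lab],), (i_rel[p, lab],), params.effective_k_close)
            )
            reactions.append(  # joint departure: loader takes the clamp with it
                Reaction(
                    (i_rel[p, lab],),
                    (i_rfc_sol[p], i_clamp[lab], i_dna),
                    k_off[p],
                )
            )
            if with_poldelta:
                reactions.append(  # capture occludes unloading; loader lingers
                    Reaction(
                        (i_rel[p, lab], i_poldelta),
                        (i_holo[lab], i_rfc_post[p]),
                        params.k_capture,
                    )
                )
            if with_slide:
                reactions.append(
                    Reaction(
                        (i_rel[p, lab],),
                        (i_escaped[lab], i_rfc_vac[p]),
                        params.k_slide,
                        tag="slide",
                    )
                )
            if with_sx:
                for src in (i_open[p, lab], i_notch[p, lab], i_rel[p, lab]):
                    reactions.append(
                        Reaction(
                            (src,),
                            (i_exchanged[lab], i_rfc_vac[p]),
                            params.k_subunit_exchange,
                            tag="sx",
                        )
                    )
        if with_poldelta:  # post-capture loader dissociates at its own rate
            reactions.append(Reaction((i_rfc_post[p],), (i_rfc_sol[p],), k_off[p]))
        if with_slide or with_sx:
            reactions.append(
                Reaction((i_rfc_vac[p],), (i_rfc_sol[p], i_dna), k_off[p])
            )

    fret = np.zeros(len(species))
    for p in POPS:
        fret[i_open[p, "lab"]] = weights["open"]
        fret[i_notch[p, "lab"]] = weights["notched"]
        fret[i_rel[p, "lab"]] = weights["released"]
    if with_poldelta:
        fret[i_holo["lab"]] = weights["holoenzyme"]

    conservation: dict[str, tuple[int, ...]] = {}
    dna_members = [i_dna] + [i_open[k] for k in i_open] + [i_notch[k] for k in i_notch] \
        + [i_rel[k] for k in i_rel] + list(i_holo.values()) + list(i_rfc_vac.values())
    conservation["dna"] = tuple(dna_members)
    loader_members = list(i_rfc_sol.values()) + [i_open[k] for k in i_open] \
        + [i_notch[k] for k in i_notch] + [i_rel[k] for k in i_rel] \
        + list(i_rfc_post.values()) + list(i_rfc_vac.values())
    conservation["loader"] = tuple(loader_members)
    for lab in LABELS:
        members = [i_clamp[lab]] + [i_open[p, lab] for p in POPS] \
            + [i_notch[p, lab] for p in POPS] + [i_rel[p, lab] for p in POPS]
        if with_poldelta:
            members.append(i_holo[lab])
        if with_slide:
            members.append(i_escaped[lab])
        if with_sx:
            members.append(i_exchanged[lab])
        conservation[f"clamp_{lab}"] = tuple(members)
    if with_poldelta:
        conservation["poldelta"] = tuple([i_poldelta] + list(i_holo.values()))

    return ReactionNetwork(
        species=species,
        reactions=reactions,
        fret_coefficients=fret,
        clamp_pool_indices=tuple(i_clamp.values()),
        k_d_partition=params.K_d_rfc_pcna,
        conservation=conservation,
    )
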