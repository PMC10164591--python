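"""Continuous-time stochastic simulation of deadenylation.

The model is an exact stochastic simulation (Gillespie direct method) over a
population of explicit RNA molecules and explicit enzyme agents.  Events are:

* **bind** — a free complex engages the 3' end of an unbound molecule.  The
  association propensity is ``k_on * [free enzyme] * m``, where ``m`` is a
  per-molecule multiplier set by effector occupancy (Cup raises it, a
  PABPC-covered 3' end lowers it).  An engagement is *tethered* when it is
  mediated by SRE-bound Smaug and the complex carries the NOT module.
* **remove one nt** — an engaged complex removes a single 3'-terminal A at
  rate ``k_cat_ccr4 + k_cat_caf1`` (active subunits only), scaled by
  ``1 - theta_dead`` when exactly one subunit is catalytically dead and by
  ``pabpc_stim`` when the tail is PABPC-covered.
* **dissociate** — an engaged complex leaves at ``k_off``, scaled by
  ``tether_off_scale`` for a tethered engagement (the processive regime).
* **handoff** — a complex sitting on a fully deadenylated molecule moves to
  a new substrate after an exponential wait at ``handoff_rate``, rebinding
  instantaneously.

Effector binding itself is treated as a fast pre-equilibrium: occupancy
flags are drawn once at t = 0 from the equilibrium occupancy ``C/(C+Kd)``,
mirroring assay protocols that pre-incubate RNA and effectors before the
enzyme is added.
"""

from __future__ import annotations

import math

import numpy as np

from .types import (
    Curve,
    EffectorSpec,
    EnzymeSpec,
    InvalidInputError,
    KineticParams,
    PopulationState,
    SubstrateSpec,
    TimeCourseEnsemble,
)

__all__ = ["effector_occupancy", "pabpc_load", "simulate", "MOLECULES_PER_NM"]

#: default agent-count scale used by scenario builders (molecules per nM)
MOLECULES_PER_NM = 100

_BUF = 1 << 15


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def effector_occupancy(effector: EffectorSpec, substrate: SubstrateSpec) -> float:
    """Equilibrium occupancy of an effector on its substrate site.

    Returns ``conc / (conc + kd)``.  For Smaug the occupancy is zero when the
    substrate has no functional Smaug recognition element.
    """
    if effector.conc < 0:
        raise InvalidInputError("effector concentration must be >= 0")
    if effector.kd <= 0:
        raise InvalidInputError("effector kd must be > 0")
    if effector.kind == "smaug" and (substrate.n_sre == 0 or not substrate.sre_functional):
        return 0.0
    return effector.conc / (effector.conc + effector.kd)


def pabpc_load(tail_length: int, params: KineticParams, conc: float, kd: float = 10.0) -> int:
    """Expected number of PABPC copies packed on a poly(A) tail.

    The tail offers ``floor(tail_length / pabpc_footprint)`` non-overlapping
    sites; each is occupied with probability ``conc/(conc+kd)`` and the
    expected copy number is rounded half up.  Monotone non-decreasing in both
    ``conc`` and ``tail_length``.
    """
    if params.pabpc_footprint <= 0:
        raise InvalidInputError("pabpc_footprint must be > 0")
    if tail_length < 0:
        raise InvalidInputError("tail_length must be >= 0")
    if conc < 0:
        raise InvalidInputError("conc must be >= 0")
    sites = tail_length // params.pabpc_footprint
    occ = conc / (conc + kd)
    return min(_round_half_up(occ * sites), sites)


def _binding_weights(smaug_on: bool, cup_on: bool, pab: int, params: KineticParams,
                     interaction: bool) -> tuple[float, float]:
    """Per-molecule association weights (untethered, tethered).

    Cup scales the on-rate; Smaug tethering makes the resulting engagement
    resistant to dissociation.  With ``interaction=True`` (the default
    mechanism) a co-occupied molecule recruits the complex at the Cup-boosted
    rate *and* every engagement is tethered: co-occupancy enables both
    effects simultaneously.  With ``interaction=False`` there is no term in
    which the two effects combine — a co-occupied molecule behaves exactly
    like a Smaug-only molecule (the stronger single effect), which serves as
    the no-interaction null for the additive-baseline test.
    """
    base = 1.0
    if pab >= 1:
        base *= params.pabpc_end_block
    eff = params.pabpc_recruit_block ** max(pab - 1, 0)
    if smaug_on and cup_on:
        if interaction:
            return 0.0, base * eff * params.cup_on_scale
        return 0.0, base * eff
    if smaug_on:
        return 0.0, base * eff
    if cup_on:
        return base * eff * params.cup_on_scale, 0.0
    return base, 0.0


def simulate(substrate: SubstrateSpec, enzyme: EnzymeSpec, effectors=(),
             params: KineticParams | None = None, grid=None, n_molecules: int = 1000,
             seed: int = 0, *, pre_bound: bool = False,
             interaction: bool = True) -> TimeCourseEnsemble:
    """Exact stochastic simulation of a deadenylation time course.

    Parameters
    ----------
    substrate, enzyme, effectors, params
        Reaction specification.  At most one effector per kind.
    grid
        Strictly increasing sampling times in seconds; the population state
        is recorded at each grid time.
    n_molecules
        Number of explicit RNA agents.  Enzyme agents are derived from the
        nM concentration ratio, rounding half up.
    seed
        Seed for the single pseudo-random stream of the call.
    pre_bound
        If True, every enzyme agent starts engaged on a distinct random
        molecule at t = 0 (emulating pre-incubated, instantaneous binding in
        burst experiments).
    interaction
        Whether Smaug and Cup act cooperatively on co-occupied molecules
        (see :func:`_binding_weights`).
    """
    params = params or KineticParams()
    if grid is None or len(grid) == 0:
        raise InvalidInputError("grid must be non-empty")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise InvalidInputError("grid must be strictly increasing")
    if grid[0] < 0:
        raise InvalidInputError("grid times must be >= 0")
    if n_molecules < 1:
        raise InvalidInputError("n_molecules must be >= 1")
    if substrate.initial_conc <= 0:
        raise InvalidInputError("substrate initial_conc must be > 0 to set the agent scale")

    effectors = tuple(effectors)
    kinds = [e.kind for e in effectors]
    if len(set(kinds)) != len(kinds):
        raise InvalidInputError("at most one effector per kind")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    N = int(n_molecules)
    scale = N / substrate.initial_conc          # molecules per nM
    n_enz = _round_half_up(enzyme.conc * scale)
    L0 = substrate.tail_length0
    fp = params.pabpc_footprint

    # --- effector occupancy flags (fast pre-equilibrium) -------------------
    occ = {e.kind: effector_occupancy(e, substrate) for e in effectors}
    smaug_f = rng.random(N) < occ.get("smaug", 0.0)
    cup_f = rng.random(N) < occ.get("cup", 0.0)
    if "pabpc" in occ:
        pab = rng.binomial(L0 // fp, occ["pabpc"], size=N).astype(np.int64)
    else:
        pab = np.zeros(N, dtype=np.int64)

    tails = np.full(N, L0, dtype=np.int64)
    mol_bound = np.zeros(N, dtype=bool)

    # --- effective rate constants ------------------------------------------
    kcat = (params.k_cat_ccr4 if enzyme.ccr4_active else 0.0) + \
           (params.k_cat_caf1 if enzyme.caf1_active else 0.0)
    n_active = int(enzyme.ccr4_active) + int(enzyme.caf1_active)
    if n_active == 1:
        kcat *= (1.0 - params.theta_dead)
    koff_u = params.k_off
    koff_t = params.k_off * params.tether_off_scale
    stim = params.pabpc_stim
    handoff = params.handoff_rate
    kon_per = params.k_on / scale               # per (agent pair) propensity
    tether_enabled = enzyme.has_not_module

    # --- unbound-molecule registry, grouped into weight classes ------------
    # class key: (smaug-tether usable, cup flag, pabpc copies)
    cls_of: dict[tuple, int] = {}
    cls_members: list[list[int]] = []
    cls_u: list[float] = []
    cls_t: list[float] = []
    mol_cid = np.full(N, -1, dtype=np.int64)
    mol_pos = np.zeros(N, dtype=np.int64)

    def class_id(m: int) -> int:
        s_on = bool(smaug_f[m]) and tether_enabled
        key = (s_on, bool(cup_f[m]), int(pab[m]))
        cid = cls_of.get(key)
        if cid is None:
            u, t = _binding_weights(key[0], key[1], key[2], params, interaction)
            cid = len(cls_members)
            cls_of[key] = cid
            cls_members.append([])
            cls_u.append(u)
            cls_t.append(t)
        return cid

    W_u = 0.0
    W_t = 0.0

    def registry_add(m: int) -> None:
        nonlocal W_u, W_t
        cid = class_id(m)
        lst = cls_members[cid]
        mol_cid[m] = cid
        mol_pos[m] = len(lst)
        lst.append(m)
        W_u += cls_u[cid]
        W_t += cls_t[cid]

    def registry_remove(m: int) -> None:
        nonlocal W_u, W_t
        cid = mol_cid[m]
        lst = cls_members[cid]
        pos = mol_pos[m]
        last = lst[-1]
        lst[pos] = last
        mol_pos[last] = pos
        lst.pop()
        mol_cid[m] = -1
        W_u -= cls_u[cid]
        W_t -= cls_t[cid]

    # --- bound-enzyme bookkeeping ------------------------------------------
    # bound class index: (tethered << 2) | (covered << 1) | done
    bcls: list[list[int]] = [[] for _ in range(8)]
    enz_mol = np.full(n_enz, -1, dtype=np.int64)
    enz_teth = np.zeros(n_enz, dtype=bool)
    enz_b = np.full(n_enz, -1, dtype=np.int64)
    enz_pos = np.zeros(n_enz, dtype=np.int64)
    free_enz = list(range(n_enz))

    def bound_add(e: int, b: int) -> None:
        lst = bcls[b]
        enz_b[e] = b
        enz_pos[e] = len(lst)
        lst.append(e)

    def bound_remove(e: int) -> None:
        b = enz_b[e]
        lst = bcls[b]
        pos = enz_pos[e]
        last = lst[-1]
        lst[pos] = last
        enz_pos[last] = pos
        lst.pop()
        enz_b[e] = -1

    def engage(e: int, m: int, teth: bool) -> None:
        enz_mol[e] = m
        enz_teth[e] = teth
        mol_bound[m] = True
        b = (4 if teth else 0) | (2 if pab[m] >= 1 else 0) | (1 if tails[m] == 0 else 0)
        bound_add(e, b)

    # initial population
    for m in range(N):
        if tails[m] > 0:
            registry_add(m)
    if pre_bound and n_enz > 0:
        chosen = rng.permutation(N)[:min(n_enz, N)]
        ub = rng.random(len(chosen))
        for j, m in enumerate(chosen):
            m = int(m)
            cid = class_id(m)
            u, t = cls_u[cid], cls_t[cid]
            tot = u + t
            teth = tot > 0 and ub[j] < t / tot
            if tails[m] > 0:
                registry_remove(m)
            e = free_enz.pop()
            engage(e, m, teth)

    # --- buffered random numbers -------------------------------------------
    e_buf = rng.standard_exponential(_BUF).tolist()
    u_buf = rng.random(_BUF).tolist()
    ei = ui = 0

    states: list[PopulationState] = []

    def snapshot(time: float) -> None:
        states.append(PopulationState(
            time=float(time),
            tail_lengths=tails.copy(),
            enzyme_bound=mol_bound.copy(),
            pabpc_copies=pab.copy(),
            effector_occupied={
                "smaug": smaug_f.copy(),
                "cup": cup_f.copy(),
                "pabpc": pab > 0,
            },
        ))

    t = 0.0
    gi = 0
    G = grid.size
    while gi < G and grid[gi] <= t:
        snapshot(grid[gi])
        gi += 1
    t_end = float(grid[-1])
    n_events = 0

    while gi < G:
        nb = bcls
        # live (tail > 0) engaged complexes, by tether / coverage
        n_live_unc = len(nb[0]) + len(nb[4])
        n_live_cov = len(nb[2]) + len(nb[6])
        n_done = len(nb[1]) + len(nb[3]) + len(nb[5]) + len(nb[7])
        n_unteth = len(nb[0]) + len(nb[1]) + len(nb[2]) + len(nb[3])
        n_teth = len(nb[4]) + len(nb[5]) + len(nb[6]) + len(nb[7])

        F = len(free_enz)
        R_bind = kon_per * F * (W_u + W_t) if F else 0.0
        R_rm = kcat * (n_live_unc + stim * n_live_cov)
        R_off = koff_u * n_unteth + koff_t * n_teth
        R_hand = handoff * n_done
        R = R_bind + R_rm + R_off + R_hand
        if R <= 0.0:
            break

        if ei == _BUF:
            e_buf = rng.standard_exponential(_BUF).tolist()
            ei = 0
        dt = e_buf[ei] / R
        ei += 1
        t_new = t + dt
        while gi < G and grid[gi] < t_new:
            snapshot(grid[gi])
            gi += 1
        if gi >= G:
            break
        t = t_new

        if ui == _BUF:
            u_buf = rng.random(_BUF).tolist()
            ui = 0
        r = u_buf[ui] * R
        ui += 1

        n_events += 1
        if n_events & 0xFFFF == 0:
            # periodically rebuild the weight aggregates to cancel float drift
            W_u = sum(cls_u[c] * len(cls_members[c]) for c in range(len(cls_members)))
            W_t = sum(cls_t[c] * len(cls_members[c]) for c in range(len(cls_members)))

        if r < R_bind:
            # choose channel (untethered vs tethered), then class, then member
            x = r / (kon_per * F)
            teth = x >= W_u
            target = x - W_u if teth else x
            wlist = cls_t if teth else cls_u
            cid_sel = -1
            acc = 0.0
            for c in range(len(cls_members)):
                n_c = len(cls_members[c])
                if n_c:
                    w = wlist[c]
                    if w > 0.0:
                        acc += w * n_c
                        cid_sel = c
                        if target < acc:
                            break
            if cid_sel < 0:
                continue
            lst = cls_members[cid_sel]
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            m = lst[min(int(u_buf[ui] * len(lst)), len(lst) - 1)]
            ui += 1
            registry_remove(m)
            e = free_enz.pop()
            engage(e, m, teth)
        elif r < R_bind + R_rm:
            x = r - R_bind
            lst, b = None, -1
            acc = 0.0
            for b_try, w in ((0, kcat), (4, kcat), (2, kcat * stim), (6, kcat * stim)):
                n_b = len(nb[b_try])
                if n_b:
                    acc += w * n_b
                    lst, b = nb[b_try], b_try
                    if x < acc:
                        break
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            e = lst[min(int(u_buf[ui] * len(lst)), len(lst) - 1)]
            ui += 1
            m = enz_mol[e]
            tails[m] -= 1
            tl = tails[m]
            cap = tl // fp
            if pab[m] > cap:
                pab[m] = cap
            new_b = (b & 4) | (2 if pab[m] >= 1 else 0) | (1 if tl == 0 else 0)
            if new_b != b:
                bound_remove(e)
                bound_add(e, new_b)
        elif r < R_bind + R_rm + R_off:
            x = r - R_bind - R_rm
            groups = [(koff_u, 0), (koff_u, 1), (koff_u, 2), (koff_u, 3),
                      (koff_t, 4), (koff_t, 5), (koff_t, 6), (koff_t, 7)]
            lst = None
            acc = 0.0
            for w, b in groups:
                n_b = len(nb[b])
                if n_b:
                    acc += w * n_b
                    lst = nb[b]
                    if x < acc:
                        break
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            e = lst[min(int(u_buf[ui] * len(lst)), len(lst) - 1)]
            ui += 1
            m = enz_mol[e]
            bound_remove(e)
            enz_mol[e] = -1
            mol_bound[m] = False
            free_enz.append(e)
            if tails[m] > 0:
                registry_add(m)
        else:
            # handoff: a complex on a finished molecule rebinds instantly
            done_lists = [nb[1], nb[3], nb[5], nb[7]]
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            pick = int(u_buf[ui] * n_done)
            ui += 1
            pick = min(pick, n_done - 1)
            for lst in done_lists:
                if pick < len(lst):
                    e = lst[pick]
                    break
                pick -= len(lst)
            m_old = enz_mol[e]
            bound_remove(e)
            enz_mol[e] = -1
            mol_bound[m_old] = False
            # instantaneous rebinding to a uniformly chosen free substrate;
            # recruitment kinetics are already absorbed in handoff_rate
            n_avail = sum(len(lst) for lst in cls_members)
            if n_avail == 0:
                free_enz.append(e)
                continue
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            pick = min(int(u_buf[ui] * n_avail), n_avail - 1)
            ui += 1
            cid_sel = -1
            for c in range(len(cls_members)):
                n_c = len(cls_members[c])
                if pick < n_c:
                    cid_sel = c
                    break
                pick -= n_c
            lst = cls_members[cid_sel]
            m = lst[pick]
            tot = cls_u[cid_sel] + cls_t[cid_sel]
            if tot <= 0.0:
                free_enz.append(e)
                continue
            if ui == _BUF:
                u_buf = rng.random(_BUF).tolist()
                ui = 0
            teth = u_buf[ui] < cls_t[cid_sel] / tot
            ui += 1
            registry_remove(m)
            engage(e, m, teth)

    # grid points beyond the last event (absorbing state)
    while gi < G:
        snapshot(grid[gi])
        gi += 1

    return TimeCourseEnsemble(
        substrate=substrate,
        enzyme=enzyme,
        effectors=effectors,
        params=params,
        grid=grid,
        states=states,
        seed=int(seed),
        ground_truth={"params": params, "n_molecules": N, "n_enzymes": n_enz,
                      "scale": scale, "pre_bound": pre_bound,
                      "interaction": interaction},
    )


def fraction_curve(ensemble: TimeCourseEnsemble) -> Curve:
    """Fraction of fully deadenylated molecules on the sampling grid."""
    vals = np.array([float(np.mean(s.tail_lengths == 0)) for s in ensemble.states])
    return Curve(ensemble.grid.copy(), vals)
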