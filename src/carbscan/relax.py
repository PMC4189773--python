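"""FIRE geometry relaxation of movable atoms under the nonbonded model.

FIRE (Fast Inertial Relaxation Engine) integrates damped Newtonian
dynamics with velocity mixing: while the power P = F.v stays positive the
time step grows and the mixing weakens; on overshoot (P <= 0) the velocity
is zeroed and the step shrinks. Parameters follow the original published
scheme (f_inc 1.1, f_dec 0.5, alpha_start 0.1, f_alpha 0.99, N_min 5).

Because the energy model is nonbonded-only, covalent geometry of movable
atoms is maintained with harmonic restraints on 1-2 (bond) and 1-3
(geminal) distances to their input values — a simple internal-coordinate
restraint that is equivalent to bond + angle restraints at fixed bond
lengths. Nonbonded terms exclude 1-2/1-3 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import MinimizationError
from .energy import ForceFieldParameters, load_default_forcefield
from .ligand import LigandTemplate
from .model import Structure

__all__ = [
    "MinimizerSettings",
    "fire_minimize",
    "relax_binding_site",
    "nonbonded_system",
]

_COV_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "ZN": 1.22, "P": 1.07,
}


@dataclass
class MinimizerSettings:
    """FIRE settings; tolerance is the max force component (kcal/mol/A)."""

    dt_init: float = 0.02
    dt_max: Optional[float] = None  # default 10 * dt_init
    f_inc: float = 1.1
    f_dec: float = 0.5
    alpha_start: float = 0.1
    f_alpha: float = 0.99
    n_min: int = 5
    force_tolerance: float = 0.05
    max_iterations: int = 5000

    def __post_init__(self):
        if not (0.0 < self.f_dec < 1.0 < self.f_inc):
            raise ValueError("need 0 < f_dec < 1 < f_inc")
        if not (0.0 < self.alpha_start < 1.0):
            raise ValueError("alpha_start must be in (0, 1)")
        if self.force_tolerance <= 0:
            raise ValueError("force tolerance must be positive")
        if self.dt_max is None:
            self.dt_max = 10.0 * self.dt_init


def fire_minimize(
    x0: np.ndarray,
    objective: Callable[[np.ndarray], tuple[float, np.ndarray]],
    settings: Optional[MinimizerSettings] = None,
) -> tuple[np.ndarray, dict]:
    """Minimize ``objective`` (returning energy and gradient) from ``x0``.

    Returns the lowest-energy configuration visited and a trajectory
    summary (iterations, convergence flag, initial/final energy, final
    max force component). The returned energy never exceeds the initial
    energy.
    """
    st = settings or MinimizerSettings()
    x = np.asarray(x0, float).copy()
    e, g = objective(x)
    if not np.isfinite(e) or not np.all(np.isfinite(g)):
        raise MinimizationError(
            "non-finite energy or gradient at the start (severe clash?); "
            "pre-separate the atoms before relaxing"
        )
    best_x, best_e = x.copy(), e
    v = np.zeros_like(x)
    dt = st.dt_init
    alpha = st.alpha_start
    n_pos = 0
    converged = False
    fmax = float(np.max(np.abs(g)))
    it = 0
    e0 = e
    for it in range(1, st.max_iterations + 1):
        f = -g
        fmax = float(np.max(np.abs(f)))
        if fmax <= st.force_tolerance:
            converged = True
            break
        p = float(np.dot(f, v))
        if p > 0.0:
            n_pos += 1
            if n_pos > st.n_min:
                dt = min(dt * st.f_inc, st.dt_max)
                alpha *= st.f_alpha
        else:
            n_pos = 0
            dt *= st.f_dec
            alpha = st.alpha_start
            v[:] = 0.0
        v = v + dt * f
        fn = float(np.linalg.norm(f))
        vn = float(np.linalg.norm(v))
        if fn > 0.0:
            v = (1.0 - alpha) * v + alpha * vn * f / fn
        x = x + dt * v
        e, g = objective(x)
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            # step into a singularity: back off and restart from best
            x = best_x.copy()
            e, g = objective(x)
            v[:] = 0.0
            dt *= st.f_dec
            continue
        if e < best_e:
            best_e = e
            best_x = x.copy()
    info = {
        "iterations": it,
        "converged": converged,
        "initial_energy": e0,
        "final_energy": best_e,
        "final_fmax": fmax,
    }
    return best_x, info


# ---------------------------------------------------------------------------
# Structure-level relaxation


def _detect_bonds(
    s: Structure, ligand_templates: Optional[dict[str, LigandTemplate]] = None
) -> list[tuple[int, int]]:
    """Covalent bonds by covalent-radius distance criterion (global index)."""
    atoms = [(r, a) for r, a in s.atoms()]
    xyz = np.array([a.position for _, a in atoms])
    if len(atoms) < 2:
        return []
    tree = cKDTree(xyz)
    bonds: list[tuple[int, int]] = []
    for i, j in tree.query_pairs(2.6):
        ri, ai = atoms[i]
        rj, aj = atoms[j]
        # metals are nonbonded (coordination is handled electrostatically)
        if ri.is_metal or rj.is_metal:
            continue
        # across residues only peptide (C-N) and disulfide (SG-SG) bonds
        # count as covalent; anything else close is a clash, not a bond
        if ri.key != rj.key:
            names = {ai.name, aj.name}
            peptide = names == {"C", "N"} and ri.chain_id == rj.chain_id \
                and abs(ri.number - rj.number) == 1
            disulfide = ai.name == "SG" and aj.name == "SG"
            if not (peptide or disulfide):
                continue
        lim = _COV_RADII.get(ai.element, 0.77) + _COV_RADII.get(aj.element, 0.77) + 0.45
        if np.linalg.norm(ai.position - aj.position) <= lim:
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def nonbonded_system(
    s: Structure,
    movable_mask: Sequence[bool],
    ff: Optional[ForceFieldParameters] = None,
    k_bond: float = 300.0,
    k_geminal: float = 60.0,
    ligand_templates: Optional[dict[str, LigandTemplate]] = None,
) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Build an objective over the movable atoms' flattened coordinates.

    Terms: Coulomb + LJ over pairs with >= 1 movable atom (1-2/1-3
    excluded), harmonic restraints on 1-2 and 1-3 distances involving a
    movable atom. Frozen coordinates are baked in as constants.
    """
    ff = ff or load_default_forcefield()
    atoms = [a for _, a in s.atoms()]
    n = len(atoms)
    mask = np.asarray(movable_mask, bool)
    if mask.shape != (n,):
        raise ValueError(f"movable mask has {mask.shape} entries for {n} atoms")
    if not mask.any():
        raise ValueError("movable mask is empty")
    xyz0 = np.array([a.position for a in atoms])
    q = np.array([a.charge if a.charge is not None else np.nan for a in atoms])
    if np.any(np.isnan(q)):
        raise MinimizationError("structure not parameterized; run assign_parameters")
    eps_t = np.array([ff.vdw_types[a.vdw_type][0] for a in atoms])
    sig_t = np.array([ff.vdw_types[a.vdw_type][1] for a in atoms])

    bonds = _detect_bonds(s, ligand_templates)
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonds:
        neigh[i].add(j)
        neigh[j].add(i)
    excluded: set[tuple[int, int]] = set(bonds)
    geminal: set[tuple[int, int]] = set()
    for k_, nb in neigh.items():
        nb_l = sorted(nb)
        for a_i in range(len(nb_l)):
            for b_i in range(a_i + 1, len(nb_l)):
                pair = (nb_l[a_i], nb_l[b_i])
                geminal.add(pair)
                excluded.add(pair)

    movable_idx = np.where(mask)[0]
    # nonbonded pair list: at least one movable, not excluded
    nb_pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i in movable_idx:
        for j in range(n):
            if j == i:
                continue
            pair = (min(i, j), max(i, j))
            if pair in seen or pair in excluded:
                continue
            seen.add(pair)
            nb_pairs.append(pair)
    nb_i = np.array([p[0] for p in nb_pairs], dtype=int)
    nb_j = np.array([p[1] for p in nb_pairs], dtype=int)
    qq = ff.coulomb_constant * q[nb_i] * q[nb_j]
    eps_ij = np.sqrt(eps_t[nb_i] * eps_t[nb_j])
    sig_ij = 0.5 * (sig_t[nb_i] + sig_t[nb_j])

    def restraint_pairs(pairs: set[tuple[int, int]], k: float):
        sel = [(i, j) for i, j in pairs if mask[i] or mask[j]]
        ii = np.array([p[0] for p in sel], dtype=int)
        jj = np.array([p[1] for p in sel], dtype=int)
        r0 = (
            np.linalg.norm(xyz0[ii] - xyz0[jj], axis=1)
            if len(sel)
            else np.zeros(0)
        )
        return ii, jj, r0, k

    b_i, b_j, b_r0, _ = restraint_pairs(set(bonds), k_bond)
    g_i, g_j, g_r0, _ = restraint_pairs(geminal, k_geminal)

    dd = ff.dielectric_model == "distance_dependent"
    k_die = ff.dielectric_k
    pos = xyz0.copy()
    idx_map = {int(g): k for k, g in enumerate(movable_idx)}

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        xm = x.reshape(-1, 3)
        pos[movable_idx] = xm
        grad = np.zeros_like(pos)
        energy = 0.0

        def accumulate(ii, jj, de_dr_fn, e_fn):
            nonlocal energy
            if len(ii) == 0:
                return
            dv = pos[ii] - pos[jj]
            r = np.linalg.norm(dv, axis=1)
            r = np.maximum(r, 1e-6)
            e = e_fn(r)
            de = de_dr_fn(r)
            energy += float(e.sum())
            gvec = (de / r)[:, None] * dv
            np.add.at(grad, ii, gvec)
            np.add.at(grad, jj, -gvec)

        if len(nb_i):
            dv = pos[nb_i] - pos[nb_j]
            r = np.maximum(np.linalg.norm(dv, axis=1), 1e-6)
            if dd:
                e_el = qq / (k_die * r * r)
                de_el = -2.0 * qq / (k_die * r**3)
            else:
                e_el = qq / (k_die * r)
                de_el = -qq / (k_die * r * r)
            sr6 = (sig_ij / r) ** 6
            e_lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
            de_lj = 4.0 * eps_ij * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            energy += float(e_el.sum() + e_lj.sum())
            gvec = ((de_el + de_lj) / r)[:, None] * dv
            np.add.at(grad, nb_i, gvec)
            np.add.at(grad, nb_j, -gvec)

        accumulate(
            b_i, b_j,
            lambda r: 2.0 * k_bond * (r - b_r0),
            lambda r: k_bond * (r - b_r0) ** 2,
        )
        accumulate(
            g_i, g_j,
            lambda r: 2.0 * k_geminal * (r - g_r0),
            lambda r: k_geminal * (r - g_r0) ** 2,
        )
        return energy, grad[movable_idx].ravel()

    return objective


def relax_binding_site(
    complex_structure: Structure,
    movable_residues: Sequence[tuple],
    ff: Optional[ForceFieldParameters] = None,
    settings: Optional[MinimizerSettings] = None,
    ligand_templates: Optional[dict[str, LigandTemplate]] = None,
) -> tuple[Structure, dict]:
    """Relax the listed residues (by key) with everything else frozen.

    The structure must be protonated and parameterized. An empty movable
    list returns the input unchanged (identity). Frozen atoms are
    bit-identical in the output.
    """
    if not movable_residues:
        return complex_structure.copy(), {"iterations": 0, "converged": True,
                                          "initial_energy": 0.0, "final_energy": 0.0,
                                          "final_fmax": 0.0}
    keys = set()
    for k in movable_residues:
        keys.add(tuple(k) if len(k) == 3 else (k[0], k[1], ""))
    out = complex_structure.copy()
    mask = []
    found_keys = set()
    for r, _a in out.atoms():
        hit = r.key in keys
        mask.append(hit)
        if hit:
            found_keys.add(r.key)
    missing = keys - found_keys
    if missing:
        raise ValueError(f"movable residues not in structure: {sorted(missing)}")

    objective = nonbonded_system(out, mask, ff, ligand_templates=ligand_templates)
    atoms = [a for _, a in out.atoms()]
    movable_idx = [i for i, m in enumerate(mask) if m]
    x0 = np.array([atoms[i].position for i in movable_idx]).ravel()
    x, info = fire_minimize(x0, objective, settings)
    for k, i in enumerate(movable_idx):
        atoms[i].position = x.reshape(-1, 3)[k].copy()
    return out, info
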