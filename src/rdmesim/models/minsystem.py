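"""Stochastic MinD/MinE pole-to-pole oscillation model.

Five species cycle between the cytosol and the inner membrane of a
rod-shaped cell: cytosolic MinD:ATP attaches to the membrane,
cooperatively recruited by the membrane-bound MinD population (both
free membrane MinD and the MinDE complex); membrane MinD recruits
cytosolic MinE into a MinDE complex, which hydrolyses and releases
MinD:ADP and MinE back to the cytosol; cytosolic nucleotide exchange
regenerates MinD:ATP.  With the shipped rate fixture the membrane-bound
MinD population oscillates from pole to pole with a period close to 40 s
and its temporal average has a minimum near mid-cell.

Reactions (membrane voxels unless noted):

    D_atp          -> D_mem              sigma_d * (A_i / v_i)
    D_atp + D_mem  -> 2 D_mem            sigma_dD / v_i
    D_atp + DE     -> D_mem + DE         sigma_dD / v_i
    D_mem + E      -> DE                 sigma_dE / v_i
    DE             -> D_adp + E          sigma_e
    D_adp          -> D_atp  (anywhere)  sigma_adp_atp

``A_i`` is the lumped membrane area of voxel ``i`` and ``v_i`` its
lumped volume, so the attachment propensity has units 1/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..analysis import half_cell_signal, oscillation_coherence
from ..assembly import assemble_fem_operators
from ..mesh import MEMBRANE, Mesh, generate_capsule_mesh
from ..model import MassActionReaction, RDMEModel, Species

__all__ = ["MinParameters", "min_model", "min_sweep"]

_FIXTURE = Path(__file__).parent / "min_rates_huang.json"


@dataclass
class MinParameters:
    """Rate and diffusion constants of the 5-species Min model."""

    sigma_d: float  # membrane attachment, um/s
    sigma_dD: float  # cooperative recruitment, um^3/s (count convention)
    sigma_dE: float  # MinE recruitment, um^3/s
    sigma_e: float  # MinDE hydrolysis/release, 1/s
    sigma_adp_atp: float  # nucleotide exchange, 1/s
    D_cytosol: float  # um^2/s
    D_membrane: float  # um^2/s
    n_mind: int
    n_mine: int

    @classmethod
    def from_fixture(cls, path: str | Path = _FIXTURE) -> "MinParameters":
        raw = json.loads(Path(path).read_text())
        return cls(
            sigma_d=raw["sigma_d_um_per_s"],
            sigma_dD=raw["sigma_dD_um3_per_s"],
            sigma_dE=raw["sigma_dE_um3_per_s"],
            sigma_e=raw["sigma_e_per_s"],
            sigma_adp_atp=raw["sigma_adp_atp_per_s"],
            D_cytosol=raw["D_cytosol_um2_per_s"],
            D_membrane=raw["D_membrane_um2_per_s"],
            n_mind=int(raw["n_mind"]),
            n_mine=int(raw["n_mine"]),
        )

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"Min parameter {f} must be >= 0")


SPECIES_NAMES = ["MinD_c_atp", "MinD_c_adp", "MinD_m", "MinE", "MinDE"]


def min_model(
    mesh: Mesh,
    params: MinParameters | None = None,
    tspan: np.ndarray | None = None,
    seed: int = 0,
) -> RDMEModel:
    """Build the Min model on a capsule (or any membrane-labelled) mesh.

    The initial MinD:ATP and MinE populations are placed uniformly at
    random (volume-weighted, seeded); total MinD and MinE counts are
    conserved by the reaction stoichiometry.
    """
    params = params or MinParameters.from_fixture()
    if tspan is None:
        tspan = np.arange(0.0, 901.0, 1.0)
    if MEMBRANE not in set(np.unique(mesh.tri_subdomain).tolist()):
        raise ValueError("mesh has no membrane-labelled surface")

    vol_ops = assemble_fem_operators(mesh, "volume")
    surf_ops = assemble_fem_operators(mesh, "surface")
    vols = vol_ops.M_lumped
    area_per_vol = np.where(vols > 0, surf_ops.M_lumped / np.maximum(vols, 1e-300), 0.0)

    mem = frozenset({MEMBRANE})
    species = [
        Species("MinD_c_atp", params.D_cytosol, "volume"),
        Species("MinD_c_adp", params.D_cytosol, "volume"),
        Species("MinD_m", params.D_membrane, "surface", mem),
        Species("MinE", params.D_cytosol, "volume"),
        Species("MinDE", params.D_membrane, "surface", mem),
    ]
    reactions = [
        MassActionReaction(
            "attach", params.sigma_d, {"MinD_c_atp": 1}, {"MinD_m": 1},
            allowed_subdomains=mem, local_factor="mem_area_per_vol",
        ),
        MassActionReaction(
            "recruit_d", params.sigma_dD, {"MinD_c_atp": 1, "MinD_m": 1}, {"MinD_m": 2},
            allowed_subdomains=mem,
        ),
        MassActionReaction(
            "recruit_d_by_de", params.sigma_dD,
            {"MinD_c_atp": 1, "MinDE": 1}, {"MinD_m": 1, "MinDE": 1},
            allowed_subdomains=mem,
        ),
        MassActionReaction(
            "recruit_e", params.sigma_dE, {"MinD_m": 1, "MinE": 1}, {"MinDE": 1},
            allowed_subdomains=mem,
        ),
        MassActionReaction(
            "release", params.sigma_e, {"MinDE": 1}, {"MinD_c_adp": 1, "MinE": 1},
            allowed_subdomains=mem,
        ),
        MassActionReaction(
            "exchange", params.sigma_adp_atp, {"MinD_c_adp": 1}, {"MinD_c_atp": 1}
        ),
    ]

    rng = np.random.default_rng(seed)
    N = mesh.n_vertices
    u0 = np.zeros((len(species), N), dtype=np.int64)
    w = vols / vols.sum()
    u0[0] = np.bincount(rng.choice(N, size=params.n_mind, p=w), minlength=N)
    u0[3] = np.bincount(rng.choice(N, size=params.n_mine, p=w), minlength=N)

    return RDMEModel(
        mesh=mesh,
        species=species,
        reactions=reactions,
        u0=u0,
        tspan=np.asarray(tspan, dtype=float),
        volumes=vols,
        data={"mem_area_per_vol": area_per_vol},
        seed=seed,
    )


def min_sweep(
    xsep_values,
    length: float = 4.5,
    radius: float = 0.5,
    h: float = 0.3,
    t_end: float = 300.0,
    params: MinParameters | None = None,
    seeds=(0,),
    solver: str = "nsm",
    solver_options: dict | None = None,
    out_dir=None,
    on_result=None,
    n_procs: int = 1,
):
    """Division-site parameter sweep: re-mesh, simulate and score per xsep.

    Returns a list of dicts {xsep, seed, coherence, period, n_voxels}
    (failed runs are recorded with an 'error' entry and the sweep
    continues).  ``out_dir`` optionally receives one trajectory file per
    run, and ``n_procs > 1`` distributes runs over worker processes —
    batch semantics for multicore workstations.
    """
    jobs = [
        dict(
            xsep=float(xsep), seed=int(seed), length=length, radius=radius, h=h,
            t_end=t_end, params=params, solver=solver,
            solver_options=solver_options, out_dir=out_dir,
        )
        for xsep in xsep_values
        for seed in seeds
    ]
    if n_procs > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=n_procs) as pool:
            results = list(pool.map(_sweep_one, jobs))
        if on_result is not None:
            for rec in results:
                on_result(rec)
        return results
    results = []
    for job in jobs:
        rec = _sweep_one(job)
        results.append(rec)
        if on_result is not None:
            on_result(rec)
    return results


def _sweep_one(job: dict) -> dict:
    from ..analysis import find_oscillation_period
    from ..nsm import simulate_nsm

    rec = {"xsep": job["xsep"], "seed": job["seed"]}
    tspan = np.arange(0.0, job["t_end"] + 1.0, 1.0)
    try:
        mesh = generate_capsule_mesh(
            job["length"], job["radius"], job["h"], xsep=job["xsep"], seed=1
        )
        model = min_model(mesh, job["params"], tspan=tspan, seed=job["seed"])
        if job["solver"] == "dfsp":
            from ..dfsp import simulate_dfsp

            traj = simulate_dfsp(model, **(job["solver_options"] or {}))
        else:
            traj = simulate_nsm(model)
        sig = half_cell_signal("MinD_m", mesh)
        rec["coherence"] = oscillation_coherence(traj, sig, mesh)
        rec["period"] = find_oscillation_period(traj, sig, mesh)
        rec["n_voxels"] = mesh.n_vertices
        if job["out_dir"] is not None:
            from ..traj_io import save_trajectory

            save_trajectory(
                Path(job["out_dir"]) / f"min_xsep{job['xsep']:g}_seed{job['seed']}.h5",
                traj,
                meta={"xsep": job["xsep"]},
            )
    except Exception as exc:  # failed runs are recorded, sweep continues
        rec["error"] = str(exc)
    return rec
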