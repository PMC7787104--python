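"""Triage pipeline: reads merged intensities, corrects anisotropy,
branches over TNCS-order hypotheses, tests twinning under each, expands
to subgroups where twinning is indicated, and records every step as a
hypothesis node in a DAG whose leaves are phasing-ready datasets."""

from __future__ import annotations

import hashlib
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import anisotropy as aniso_mod
from . import intensity_stats as istats
from . import symmetry
from . import tncs as tncs_mod
from . import twinning as twin_mod
from .dag import Dag, content_id
from .reflection_data import ReflectionDataset, read_reflections, write_reflections

__all__ = ["PipelineConfig", "run_xtricorder", "resume", "logical_scenario_dag"]

log = logging.getLogger("refltriage")


@dataclass
class PipelineConfig:
    input: str | None = None
    column_hints: dict | None = None
    d_max: float | None = None            # resolution window applied on read
    d_min: float | None = None
    nbins: int = 20
    patterson_d_max: float = 10.0
    patterson_d_min: float = 4.0
    patterson_threshold: float = 0.20
    origin_radius: float = 5.0
    m_max: int = 8
    n_tncs_candidates: int = 3            # non-trivial hypotheses kept
    twin_p_threshold: float = 1e-6
    outlier_p_cut: float = 1e-6
    out_dir: str = "refltriage_out"
    seed: int = 0
    verbosity: str = "summary"            # summary | verbose | debug
    threads: int = 1                      # advisory; results are degree-independent
    composition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _data_checksum(dataset: ReflectionDataset) -> str:
    h = hashlib.sha256()
    h.update(dataset.hkl.tobytes())
    h.update(np.ascontiguousarray(dataset.I).tobytes())
    h.update(np.ascontiguousarray(dataset.sigI).tobytes())
    return h.hexdigest()[:12]


class _Run:
    """One pipeline execution; reuses nodes from a previous DAG when their
    content-derived ids match (resume support)."""

    def __init__(self, config: PipelineConfig, previous: Dag | None = None):
        self.config = config
        self.dag = Dag()
        self.previous = previous
        self.reused: list[str] = []
        self.computed: list[str] = []
        self.outputs: list[str] = []
        os.makedirs(config.out_dir, exist_ok=True)

    # -- node helper ---------------------------------------------------
    def stage(self, kind: str, key, parents: list[str], compute, rank: float = 0.0) -> str:
        nid = content_id(kind, key, parents)
        if self.previous is not None and nid in self.previous:
            payload = self.previous.node(nid).payload
            prev_rank = self.previous.node(nid).rank
            self.dag.add_node(kind, payload=payload, parents=parents, rank=prev_rank,
                              node_id=nid)
            self.reused.append(nid)
            log.debug("reused node %s", nid)
            return nid
        payload = compute()
        self.dag.add_node(kind, payload=payload, parents=parents, rank=rank, node_id=nid)
        self.computed.append(nid)
        log.debug("computed node %s", nid)
        return nid

    def dataset_path(self, nid: str, fmt: str = "tsv") -> str:
        return os.path.join(self.config.out_dir, f"{nid}.{fmt}")

    def save_dataset(self, nid: str, dataset: ReflectionDataset):
        for fmt in ("tsv", "mtz"):
            path = self.dataset_path(nid, fmt)
            write_reflections(dataset, path, format=fmt)
            self.outputs.append(path)

    def load_or(self, nid: str, maker):
        """Reload a cached per-node dataset on resume, else compute+save."""
        path = self.dataset_path(nid)
        if nid in self.reused and os.path.exists(path):
            return read_reflections(path)
        ds = maker()
        self.save_dataset(nid, ds)
        return ds


def _apply_resolution_window(dataset: ReflectionDataset, config: PipelineConfig):
    if config.d_max is None and config.d_min is None:
        return dataset
    d = dataset.d_spacings()
    keep = np.ones(dataset.n, dtype=bool)
    if config.d_max is not None:
        keep &= d <= config.d_max
    if config.d_min is not None:
        keep &= d >= config.d_min
    return dataset.copy_with(hkl=dataset.hkl[keep], I=dataset.I[keep],
                             sigI=dataset.sigI[keep])


def run_xtricorder(
    config: PipelineConfig,
    dataset: ReflectionDataset | None = None,
    previous: Dag | None = None,
) -> dict:
    """Run the full triage and return {'dag', 'outputs', 'leaves', ...}."""
    t0 = time.time()
    run = _Run(config, previous=previous)
    if dataset is None:
        if config.input is None:
            raise ValueError("config.input or an in-memory dataset is required")
        dataset = read_reflections(config.input, config.column_hints)
    dataset = _apply_resolution_window(dataset, config)
    pg = dataset.point_group
    log.info("input: %d unique reflections, Laue group %s", dataset.n, pg.symbol)

    # crystal and data nodes -------------------------------------------
    crystal_id = run.stage(
        "crystal",
        {"composition": config.composition},
        [],
        lambda: {"composition": config.composition},
    )
    checksum = _data_checksum(dataset)

    def data_payload():
        fw = istats.detect_french_wilson(dataset)
        return {
            "n_reflections": dataset.n,
            "cell": list(dataset.cell.as_tuple()),
            "laue": pg.symbol,
            "wavelength": dataset.wavelength,
            "checksum": checksum,
            "french_wilson": fw,
        }

    data_id = run.stage("data", {"checksum": checksum}, [crystal_id], data_payload)

    # anisotropy (computed once, in the parent symmetry) ---------------
    binning = istats.make_binning(dataset.s_squared(), nbins=config.nbins)
    aniso_state = {}

    def aniso_payload():
        res = aniso_mod.refine_anisotropy(dataset, binning)
        aniso_state["B"] = res["B"]
        return {
            "B": res["B"].B.tolist(),
            "eigenvalues": res["B"].eigenvalues().tolist(),
            "converged": res["converged"],
            "n_basis": len(res["B"].basis),
        }

    aniso_id = run.stage(
        "anisotropy", {"checksum": checksum, "nbins": config.nbins}, [data_id],
        aniso_payload,
    )
    if "B" not in aniso_state:  # reused node: rebuild tensor from payload
        basis = aniso_mod.constrained_basis(pg, dataset.cell)
        Bmat = np.array(run.dag.node(aniso_id).payload["B"])
        coeffs = np.array([np.tensordot(Bmat, E) for E in basis])
        aniso_state["B"] = aniso_mod.AnisoTensor(B=Bmat, basis=basis, coefficients=coeffs)
    corrected = run.load_or(aniso_id, lambda: aniso_mod.apply_correction(
        dataset, aniso_state["B"]))
    log.info("anisotropy eigenvalues: %s",
             np.round(np.linalg.eigvalsh(aniso_state["B"].B), 2).tolist())

    # TNCS order hypotheses --------------------------------------------
    eps_sym = corrected.epsilon()
    norm_state = istats.estimate_sigma_curve(
        corrected, binning, eps_sym=eps_sym, p_cut=config.outlier_p_cut
    )
    pmap = tncs_mod.patterson_map(
        corrected,
        d_max=config.patterson_d_max,
        d_min=config.patterson_d_min,
        state=norm_state,
    )
    peaks = tncs_mod.find_tncs_vectors(
        pmap, threshold_rel=config.patterson_threshold,
        origin_radius=config.origin_radius,
    )
    hypotheses = tncs_mod.infer_tncs_orders(peaks, m_max=config.m_max)
    nontrivial = [h for h in hypotheses if h["m"] > 1][: config.n_tncs_candidates]
    candidates = nontrivial + [h for h in hypotheses if h["m"] == 1]
    log.info("TNCS candidates: %s", [(h["m"], tuple(np.round(h["t"], 3))) for h in candidates])

    leaves_meta = []
    try:
        for cand in candidates:
            _run_branch(run, cand, corrected, binning, aniso_id, leaves_meta)
    except Exception:
        # keep what we have: serialize the partial dag, then re-raise
        with open(os.path.join(config.out_dir, "dag.json"), "w") as fh:
            fh.write(run.dag.serialize())
        raise

    # serialize ---------------------------------------------------------
    dag_path = os.path.join(config.out_dir, "dag.json")
    with open(dag_path, "w") as fh:
        fh.write(run.dag.serialize())
    dot_path = os.path.join(config.out_dir, "dag.dot")
    with open(dot_path, "w") as fh:
        fh.write(run.dag.to_dot())
    run.outputs += [dag_path, dot_path]
    log.info("finished in %.1f s: %d nodes, %d leaves", time.time() - t0,
             len(run.dag), len(run.dag.leaf_hypotheses()))
    return {
        "dag": run.dag,
        "outputs": run.outputs,
        "leaves": run.dag.leaf_hypotheses(),
        "reused": run.reused,
        "computed": run.computed,
        "peaks": peaks,
        "candidates": candidates,
    }


def _run_branch(run: _Run, cand: dict, corrected: ReflectionDataset,
                binning, aniso_id: str, leaves_meta: list):
    config = run.config
    m = int(cand["m"])
    t = tuple(round(float(x), 4) for x in cand["t"])
    pg = corrected.point_group
    eps_sym = corrected.epsilon()
    centric = corrected.centric()

    order_id = run.stage(
        "tncs_order", {"m": m, "t": t}, [aniso_id],
        lambda: {"m": m, "t": list(t), "score": cand.get("score", 0.0)},
    )

    # TNCS correction (identity for m = 1)
    if m > 1:
        model_holder = {}

        def tncs_payload():
            model = tncs_mod.refine_tncs(corrected, cand, binning=binning)
            model_holder["model"] = model
            return {
                "m": model.m,
                "t": list(np.round(model.t, 5)),
                "r_eff": model.r_eff,
                "sigma_rmsd": model.sigma_rmsd,
                "f0": model.f0,
                "beta": model.beta,
                "rot": list(model.rot),
                "warning": model.warning,
                "loglik": model.loglik,
            }

        corr_id = run.stage(
            "tncs_correction", {"m": m, "t": t, "nbins": config.nbins},
            [order_id], tncs_payload,
        )
        if "model" not in model_holder:
            p = run.dag.node(corr_id).payload
            model_holder["model"] = tncs_mod.TncsModel(
                m=p["m"], t=np.array(p["t"]), r_eff=p["r_eff"],
                sigma_rmsd=p["sigma_rmsd"], f0=p["f0"], beta=p["beta"],
                rot=np.array(p["rot"]), warning=p["warning"],
            )
        model = model_holder["model"]
        eps_tncs = tncs_mod.tncs_epsilon(corrected, model, binning=binning)
        twin_parent = corr_id
    else:
        model = tncs_mod.TncsModel(m=1)
        eps_tncs = np.ones(corrected.n)
        twin_parent = order_id

    state = istats.estimate_sigma_curve(
        corrected, binning, eps_sym=eps_sym, eps_tncs=eps_tncs,
        centric=centric, p_cut=config.outlier_p_cut,
    )
    moments = istats.second_moments(state)
    branch_ll = _loglik_per_reflection(corrected, state)

    def twin_payload():
        report = twin_mod.ltest_report(
            corrected, state.z, p_threshold=config.twin_p_threshold
        )
        return {
            "n_pairs": report.n_pairs,
            "mean_absL": report.mean_absL,
            "p_untwinned": report.p_untwinned,
            "p_twin_le_5pct": report.p_twin_le_5pct,
            "verdict": report.verdict,
            "curve": report.curve.tolist(),
            "second_moments": moments,
        }

    twin_id = run.stage(
        "twinning",
        {"m": m, "t": t, "p": config.twin_p_threshold},
        [twin_parent], twin_payload,
    )
    verdict = run.dag.node(twin_id).payload["verdict"]
    log.info("branch m=%d: <|L|>=%.4f p_untwinned=%.3g -> %s", m,
             run.dag.node(twin_id).payload["mean_absL"],
             run.dag.node(twin_id).payload["p_untwinned"], verdict)

    # branch leaves -----------------------------------------------------
    branch_ds = corrected.copy_with(
        I=corrected.I / eps_tncs, sigI=corrected.sigI / eps_tncs,
        provenance=list(corrected.provenance) + ([f"tncs:{m}"] if m > 1 else []),
    )
    if verdict == "twinned":
        for sub in symmetry.enumerate_proper_subgroups(pg):
            def leaf_payload(sub=sub):
                return {"subgroup": sub.label, "index": sub.index,
                        "parent_symmetry": pg.symbol, "m": m}

            leaf_id = run.stage(
                "spacegroup_expansion", {"m": m, "t": t, "subgroup": sub.label},
                [twin_id], leaf_payload, rank=branch_ll,
            )
            if leaf_id in run.computed:
                run.dag.set_rank(leaf_id, branch_ll)
            run.load_or(leaf_id, lambda sub=sub: symmetry.expand_to_subgroup(branch_ds, sub))
            leaves_meta.append(leaf_id)
    else:
        def leaf_payload():
            return {"symmetry": pg.symbol, "m": m}

        leaf_id = run.stage(
            "spacegroup", {"m": m, "t": t, "symmetry": pg.symbol},
            [twin_id], leaf_payload, rank=branch_ll,
        )
        if leaf_id in run.computed:
            run.dag.set_rank(leaf_id, branch_ll)
        run.load_or(leaf_id, lambda: branch_ds)
        leaves_meta.append(leaf_id)


def _loglik_per_reflection(dataset, state) -> float:
    mu = state.expected_intensity()
    I = np.maximum(dataset.I, 1e-12)
    centric = state.centric
    ll = np.where(
        centric,
        -0.5 * np.log(2 * np.pi * mu * I) - 0.5 * I / mu,
        -np.log(mu) - I / mu,
    )
    n = max(int(state.mask.sum()), 1)
    return float(np.sum(ll[state.mask]) / n)


def logical_scenario_dag(
    laue: str = "422",
    orders: tuple = (1, 7),
    twinned_orders: tuple = (7,),
    tncs_t: tuple = (0.0, 0.0, 1.0 / 7.0),
) -> Dag:
    """Build the hypothesis DAG for a stated branching scenario without
    numeric analysis: candidate TNCS orders, twin verdict per order, and
    subgroup expansion on twinned branches (untwinned branches keep the
    parent symmetry as their single leaf)."""
    pg = symmetry.point_group(laue)
    dag = Dag()
    crystal = dag.add_node("crystal", {"composition": {}})
    data = dag.add_node("data", {"laue": pg.symbol}, [crystal])
    aniso = dag.add_node("anisotropy", {}, [data])
    for m in orders:
        t = list(tncs_t) if m > 1 else [0.0, 0.0, 0.0]
        order_id = dag.add_node("tncs_order", {"m": m, "t": t}, [aniso])
        if m > 1:
            corr = dag.add_node("tncs_correction", {"m": m, "t": t}, [order_id])
            twin_parent = corr
        else:
            twin_parent = order_id
        twinned = m in twinned_orders
        twin = dag.add_node(
            "twinning",
            {"m": m, "verdict": "twinned" if twinned else "untwinned"},
            [twin_parent],
        )
        if twinned:
            for sub in symmetry.enumerate_proper_subgroups(pg):
                dag.add_node(
                    "spacegroup_expansion",
                    {"subgroup": sub.label, "index": sub.index, "m": m},
                    [twin],
                )
        else:
            dag.add_node("spacegroup", {"symmetry": pg.symbol, "m": m}, [twin])
    return dag


def resume(dag_file: str, config: PipelineConfig,
           dataset: ReflectionDataset | None = None) -> dict:
    """Re-run the pipeline reusing every node of a previous DAG whose
    content-derived id still matches; only missing work is recomputed."""
    with open(dag_file) as fh:
        previous = Dag.deserialize(fh.read())
    return run_xtricorder(config, dataset=dataset, previous=previous)
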