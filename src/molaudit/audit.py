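"""End-to-end audit of a generated molecule set against its training set.

Stage order mirrors the analysis workflow: filter -> (optional)
atom-count-matched downsampling -> composition/size/geometry statistics with
two-sample tests -> substructure prevalence and ring classes -> descriptors
-> latent map + KDE + clusters -> discriminator. A single global seed fans
out to per-stage seeds through a fixed derivation so any stage can be
re-run in isolation; stage failures are recorded and dependent stages are
skipped rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .chem_io import (
    BondPerceptionParams,
    assign_bond_orders_and_aromaticity,
    filter_set,
    perceive_bonds,
    read_molecules,
)
from .dataset_stats import (
    bonded_distance_distribution,
    elemental_composition,
    ks_two_sample,
    size_and_mass_distributions,
    welch_t,
)
from .descriptors import FingerprintConfig, featurize_set
from .discriminator import discriminate_sets
from .latent_space import cluster_latent, fit_latent_map, kde2d
from .molecule import Molecule, molecules_to_frame
from .resampling import downsample_to_histogram
from .soap import StructuralDescriptorConfig
from .substructure import GroupCatalog, group_prevalence, ring_profiles

log = logging.getLogger(__name__)

_STAGE_SALTS = {
    "downsample": 1,
    "latent": 2,
    "discriminator": 3,
    "fixtures": 4,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed fan-out of the global seed to per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_SALTS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class AuditConfig:
    train_path: Optional[str] = None
    generated_path: Optional[str] = None
    format: str = "xyz"
    out_dir: Optional[str] = None
    seed: int = 0
    bond_params: BondPerceptionParams = field(default_factory=BondPerceptionParams)
    # desk-scale structural descriptor; heavier settings are a config choice
    structural_cfg: StructuralDescriptorConfig = field(
        default_factory=lambda: StructuralDescriptorConfig(
            cutoff=4.0, n_radial=4, l_max=3
        )
    )
    fingerprint_cfg: FingerprintConfig = field(default_factory=FingerprintConfig)
    catalog_path: Optional[str] = None
    downsample: bool = True
    latent: bool = True
    discriminator: bool = True
    n_clusters: int = 25
    bond_pair: tuple[str, str] = ("C", "C")
    heatmaps: bool = False  # write PNG KDE heatmaps next to the report


@dataclass
class AuditReport:
    provenance: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)
    downsample_plan: Optional[dict] = None
    composition: dict = field(default_factory=dict)
    size_mass: dict = field(default_factory=dict)
    bond_distances: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    prevalence: dict = field(default_factory=dict)
    rings: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)
    discriminator: Optional[dict] = None
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_heatmap(surface, points, n_train: int, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
    for ax, pts, title in (
        (axes[0], points[:n_train], "train"),
        (axes[1], points[n_train:], "generated"),
    ):
        ax.pcolormesh(surface.x_edges, surface.y_edges, surface.density,
                      cmap="Blues", shading="auto")
        ax.scatter(pts[:, 0], pts[:, 1], s=4, c="k", alpha=0.4)
        ax.set_title(title)
        ax.set_xlabel("Structural PC1")
    axes[0].set_ylabel("Bonding PC1")
    fig.tight_layout()
    fig.savefig(out / "latent_heatmap.png", dpi=150)
    plt.close(fig)


def prepare_set(
    mols: Sequence[Molecule], cfg: AuditConfig
) -> tuple[list[Molecule], dict]:
    """Perceive bonds where needed, assign orders/aromaticity, filter."""
    out = []
    for m in mols:
        if not m.bonds and m.coords is not None and m.n_atoms > 1:
            m = perceive_bonds(m, cfg.bond_params)
        if m.smiles is None:
            m = assign_bond_orders_and_aromaticity(m)
        out.append(m)
    kept, counts = filter_set(out)
    return kept, asdict(counts) | {"n_kept": counts.n_kept}


def run_audit(
    config: AuditConfig,
    train_mols: Optional[Sequence[Molecule]] = None,
    generated_mols: Optional[Sequence[Molecule]] = None,
) -> AuditReport:
    """Run every requested stage; see the module docstring for the order."""
    report = AuditReport()
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "covalent_radius_factor": config.bond_params.covalent_radius_factor,
        "fingerprint": asdict(config.fingerprint_cfg),
    }
    if train_mols is None:
        train_mols = read_molecules(config.train_path, config.format, label="train")
    if generated_mols is None:
        generated_mols = read_molecules(
            config.generated_path, config.format, label="generated"
        )

    train, c_train = prepare_set(train_mols, config)
    gen, c_gen = prepare_set(generated_mols, config)
    report.filter_counts = {"train": c_train, "generated": c_gen}
    log.info("filter: train %s generated %s", c_train, c_gen)

    if config.downsample:
        try:
            plan = downsample_to_histogram(
                gen, train, seed=stage_seed(config.seed, "downsample")
            )
            gen = plan.apply(gen)
            report.downsample_plan = {
                "method": plan.method,
                "seed": plan.seed,
                "n_selected": int(len(plan.indices)),
                "params": plan.params,
            }
            log.info("downsample: %d generated molecules kept", len(gen))
        except Exception as exc:
            report.errors["downsample"] = str(exc)

    # --- distribution statistics -------------------------------------
    try:
        report.composition = {
            "train": elemental_composition(train).to_dict(),
            "generated": elemental_composition(gen).to_dict(),
        }
        sm_t = size_and_mass_distributions(train)
        sm_g = size_and_mass_distributions(gen)
        report.size_mass = {
            "train": {
                "mean_atom_count": sm_t.mean_atom_count,
                "mean_molecular_weight": sm_t.mean_molecular_weight,
                "molecular_weight_hist": sm_t.molecular_weight.to_frame().to_dict("list"),
            },
            "generated": {
                "mean_atom_count": sm_g.mean_atom_count,
                "mean_molecular_weight": sm_g.mean_molecular_weight,
                "molecular_weight_hist": sm_g.molecular_weight.to_frame().to_dict("list"),
            },
        }
        mw_t = [m.molecular_weight for m in train]
        mw_g = [m.molecular_weight for m in gen]
        report.tests = {
            "molecular_weight_welch": welch_t(mw_t, mw_g).to_dict(),
            "molecular_weight_ks": ks_two_sample(mw_t, mw_g).to_dict(),
        }
    except Exception as exc:
        report.errors["stats"] = str(exc)

    try:
        if all(m.coords is not None for m in train + gen):
            ea, eb = config.bond_pair
            report.bond_distances = {
                "pair": f"{ea}-{eb}",
                "train": bonded_distance_distribution(train, ea, eb).to_frame().to_dict("list"),
                "generated": bonded_distance_distribution(gen, ea, eb).to_frame().to_dict("list"),
            }
    except Exception as exc:
        report.errors["bond_distances"] = str(exc)

    # --- substructure -------------------------------------------------
    try:
        catalog = (
            GroupCatalog.from_tsv(config.catalog_path)
            if config.catalog_path
            else GroupCatalog.default()
        )
        report.prevalence = {
            "train": group_prevalence(train, catalog).to_dict(),
            "generated": group_prevalence(gen, catalog).to_dict(),
        }
        _, share_t = ring_profiles(train)
        _, share_g = ring_profiles(gen)
        report.rings = {
            "train": share_t.to_dict(),
            "generated": share_g.to_dict(),
        }
    except Exception as exc:
        report.errors["substructure"] = str(exc)

    # --- latent space -------------------------------------------------
    latent_points = None
    if config.latent:
        try:
            have_coords = all(m.coords is not None for m in train + gen)
            if not have_coords:
                raise ValueError("latent stage needs 3D coordinates on every molecule")
            species = tuple(
                sorted({e for m in train + gen for e in m.elements})
            )
            s_cfg = StructuralDescriptorConfig(
                cutoff=config.structural_cfg.cutoff,
                n_radial=config.structural_cfg.n_radial,
                l_max=config.structural_cfg.l_max,
                sigma=config.structural_cfg.sigma,
                species=species,
            )
            pairs = []
            for mols in (train, gen):
                struct = featurize_set(mols, "structural", structural_cfg=s_cfg,
                                       species=species)
                bond = featurize_set(mols, "bonding", species=species)
                pairs.append((struct, bond))
            lmap, pts = fit_latent_map(pairs)
            latent_points = pts
            surface = kde2d(pts)
            if config.heatmaps and config.out_dir:
                _write_heatmap(surface, pts, len(train), Path(config.out_dir))
            clusters = cluster_latent(pts, n_clusters=min(config.n_clusters, len(pts)))
            report.latent = {
                "explained_variance_pc1": {
                    "structural": lmap.explained_variance_pc1[0],
                    "bonding": lmap.explained_variance_pc1[1],
                },
                "n_train": len(train),
                "n_generated": len(gen),
                "kde_integral": surface.integral(),
                "cluster_sizes": clusters.sizes,
                "points": pts,
            }
        except Exception as exc:
            report.errors["latent"] = str(exc)

    # --- discriminator -------------------------------------------------
    if config.discriminator:
        try:
            rep = discriminate_sets(
                train, gen,
                fp_cfg=config.fingerprint_cfg,
                seed=stage_seed(config.seed, "discriminator"),
            )
            report.discriminator = rep.to_dict()
        except Exception as exc:
            report.errors["discriminator"] = str(exc)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        molecules_to_frame(train).to_csv(out / "train_molecules.csv", index=False)
        molecules_to_frame(gen).to_csv(out / "generated_molecules.csv", index=False)
        if latent_points is not None:
            import pandas as pd

            pd.DataFrame(
                {
                    "id": [m.id for m in train + gen],
                    "label": [m.label for m in train + gen],
                    "structural_pc1": latent_points[:, 0],
                    "bonding_pc1": latent_points[:, 1],
                }
            ).to_csv(out / "latent_coordinates.csv", index=False)
    return report
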