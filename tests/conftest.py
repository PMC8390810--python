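import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thzhdx.experiment import (
    ExperimentDesign,
    default_ubiquitin_fixture,
    simulate_experiment,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ubq_residues():
    return default_ubiquitin_fixture()


def condition_tables(
    residues,
    condition,
    scenario,
    seed,
    *,
    nominal_snr=100.0,
    storage_hours=None,
    timepoints=(3, 6, 12),
):
    """Simulate one condition's tables at each time point, with seeds spawned
    deterministically from ``seed``."""
    children = np.random.SeedSequence(seed).spawn(len(timepoints))
    tables = {}
    for child, t in zip(children, timepoints):
        design = ExperimentDesign(
            condition=condition,
            perturbation_minutes=t,
            nominal_snr=nominal_snr,
            storage_hours=storage_hours,
            seed=int(child.generate_state(1)[0]),
        )
        tables[t] = simulate_experiment(residues, design, scenario)
    return tables


def paired_run(residues, condition, scenario, seed, **kwargs):
    """GC + perturbed table sets for one seed (GC and perturbed samples get
    independent sub-seeds, like physically distinct tubes)."""
    gc_seed, pert_seed = (int(c.generate_state(1)[0]) for c in np.random.SeedSequence(seed).spawn(2))
    gc = condition_tables(residues, "GC", None, gc_seed, **kwargs)
    pert = condition_tables(residues, condition, scenario, pert_seed, **kwargs)
    return gc, pert


MINI_PDB_RESIDUES = 76


def write_mini_pdb(path, n_residues=MINI_PDB_RESIDUES, chain="A"):
    """Synthetic CA-only coordinate file: an extended pseudo-chain, one
    glycine per residue.  Stands in for a real structure in tests."""
    lines = []
    serial = 1
    for i in range(1, n_residues + 1):
        x = 3.8 * i
        lines.append(
            f"ATOM  {serial:>5}  CA  GLY {chain}{i:>4}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture()
def mini_pdb(tmp_path):
    return write_mini_pdb(tmp_path / "mini.pdb")
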