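"""Shared fixtures: random geometry helpers and heavy benchmark runs."""

from __future__ import annotations

import numpy as np
import pytest

from fraglib import assembler, fragdb, librarygen, synthetic
from fraglib.core import (
    STRETCHED_ANG_C_N_CA,
    STRETCHED_ANG_CA_C_N,
    STRETCHED_ANG_N_CA_C,
)


def random_geometry(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random valid internal-coordinate array with NaN termini."""
    g = np.empty((n, 6))
    g[:, 0] = rng.uniform(-179.0, 180.0, n)
    g[:, 1] = rng.uniform(-179.0, 180.0, n)
    g[:, 2] = rng.uniform(150.0, 180.0, n)  # near-trans peptide bonds
    g[:, 3] = STRETCHED_ANG_N_CA_C + rng.normal(0, 2.0, n)
    g[:, 4] = STRETCHED_ANG_CA_C_N + rng.normal(0, 2.0, n)
    g[:, 5] = STRETCHED_ANG_C_N_CA + rng.normal(0, 2.0, n)
    g[0, 0] = g[0, 5] = np.nan
    g[-1, 1] = g[-1, 2] = g[-1, 4] = np.nan
    return g


def random_fragment(f: int, rng: np.random.Generator,
                    entry_id: str = "frag", start: int = 0) -> librarygen.Fragment:
    g = random_geometry(f, rng)
    # interior-complete fragment (as excised from an entry's interior)
    g[0, 0] = rng.uniform(-179.0, 180.0)
    g[0, 5] = STRETCHED_ANG_C_N_CA
    g[-1, 1] = rng.uniform(-179.0, 180.0)
    g[-1, 2] = 180.0
    g[-1, 4] = STRETCHED_ANG_CA_C_N
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=f))
    ss = "".join(rng.choice(list("HEC"), size=f))
    return librarygen.Fragment(entry_id, start, seq, ss, g)


@pytest.fixture(scope="session")
def blosum():
    return librarygen.SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def small_planted():
    """A 20-entry database with a 20-residue planted target (fast checks)."""
    entries = synthetic.generate_source_database(
        20, length_range=(25, 40), seed=501)
    profile, native, provenance = synthetic.plant_target(
        entries, 20, lengths=(3,), seed=502)
    db = fragdb.build_database(entries)
    return {"entries": entries, "profile": profile, "native": native,
            "provenance": provenance, "db": db}


@pytest.fixture(scope="session")
def recovery_runs():
    """Planted-target recovery: 300-entry database, 60-residue target,
    BLO libraries (K=50, lengths 3/6/9), 10 seeded mixed assembly runs."""
    entries = synthetic.generate_source_database(300, seed=101)
    profile, native, provenance = synthetic.plant_target(
        entries, 60, lengths=(3, 6, 9), seed=102)
    db = fragdb.build_database(entries)
    libs = {f: librarygen.build_library(profile, db, f, mode="BLO", k=50)
            for f in (3, 6, 9)}
    cfg = assembler.AssemblyConfig(seed=4, n_runs=10)
    runtime = assembler._Runtime(native, libs)
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in
             root.generate_state(cfg.n_runs, dtype=np.uint32) & 0x7FFFFFFF]
    states = [assembler.run_assembly(native, libs, cfg, seed=s, runtime=runtime)
              for s in seeds]
    return {"native": native, "libs": libs, "profile": profile,
            "provenance": provenance, "states": states, "db": db}


@pytest.fixture(scope="session")
def decoy_mixed_runs():
    """Mixed 3/6/9 assembly on a planted target whose host entries are
    homology-excluded: pure-decoy libraries, all three stages active."""
    entries = synthetic.generate_source_database(200, seed=901)
    profile, native, provenance = synthetic.plant_target(
        entries, 60, lengths=(3, 6, 9), seed=902)
    hosts = {r.entry_id for r in provenance}
    db = fragdb.build_database(entries, hosts)
    libs = {f: librarygen.build_library(profile, db, f, mode="BLO", k=50)
            for f in (3, 6, 9)}
    cfg = assembler.AssemblyConfig(seed=9, n_runs=10)
    runtime = assembler._Runtime(native, libs)
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in
             root.generate_state(cfg.n_runs, dtype=np.uint32) & 0x7FFFFFFF]
    states = [assembler.run_assembly(native, libs, cfg, seed=s, runtime=runtime)
              for s in seeds]
    return {"native": native, "libs": libs, "states": states}
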