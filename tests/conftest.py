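"""Shared fixtures: synthetic archives generated once per session."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from cryoxref.fixtures import FixtureConfig, generate_archive
from cryoxref.pipeline import run_annotation
from cryoxref.snapshots import load_snapshot

FIXED_DATE = "2025-09-05"


def _make(tmp_path_factory, name: str, config: FixtureConfig) -> SimpleNamespace:
    root = tmp_path_factory.mktemp(name)
    archive_dir, snapshot_dir, gt = generate_archive(config, root)
    return SimpleNamespace(
        root=root,
        archive_dir=archive_dir,
        snapshot_dir=snapshot_dir,
        gt=gt,
        config=config,
    )


@pytest.fixture(scope="session")
def small_archive(tmp_path_factory):
    """A 12-entry archive with one entry planted across all resources."""
    return _make(tmp_path_factory, "small", FixtureConfig(n_entries=12, seed=7))


@pytest.fixture(scope="session")
def small_result(small_archive):
    return run_annotation(
        small_archive.archive_dir,
        small_archive.snapshot_dir,
        small_archive.root / "out",
        date=FIXED_DATE,
    )


@pytest.fixture(scope="session")
def small_snapshot(small_archive):
    return load_snapshot(small_archive.snapshot_dir)


@pytest.fixture(scope="session")
def big_archive(tmp_path_factory):
    """The 50-entry archive used for recovery and similarity oracles."""
    return _make(tmp_path_factory, "big", FixtureConfig(n_entries=50, seed=11))


@pytest.fixture(scope="session")
def big_result(big_archive):
    return run_annotation(
        big_archive.archive_dir,
        big_archive.snapshot_dir,
        big_archive.root / "out",
        date=FIXED_DATE,
    )
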