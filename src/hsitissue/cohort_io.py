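"""Cohort directory layout: one subdirectory per subject plus a manifest.

::

    cohort/
      manifest.json            # subjects, seed, checksums
      subject_01/
        cube.raw  cube.raw.hdr # ENVI pair
        mask.png  mask.json    # indexed mask + class map
      subject_02/ ...
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .io import read_cube, read_mask, write_cube, write_mask
from .synthetic import SyntheticSubject


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort(cohort: list, out_dir, seed: int | None = None) -> dict:
    """Write subjects to ``out_dir`` and return the manifest (also saved)."""
    out_dir = Path(out_dir)
    manifest = {"seed": seed, "subjects": {}}
    for subject in cohort:
        sdir = out_dir / subject.subject_id
        write_cube(subject.cube, sdir / "cube.raw")
        write_mask(subject.mask, sdir / "mask.png")
        manifest["subjects"][subject.subject_id] = {
            "checksums": {
                name: _sha256(sdir / name)
                for name in ("cube.raw", "cube.raw.hdr", "mask.png", "mask.json")
            }
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_cohort(cohort_dir) -> list:
    """Read every subject directory listed in the manifest (or found on disk)."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if manifest_path.exists():
        subject_ids = sorted(json.loads(manifest_path.read_text())["subjects"])
    else:
        subject_ids = sorted(p.name for p in cohort_dir.iterdir() if p.is_dir())
    if not subject_ids:
        raise FileNotFoundError(f"no subjects found under {cohort_dir}")
    cohort = []
    for sid in subject_ids:
        sdir = cohort_dir / sid
        cube = read_cube(sdir / "cube.raw")
        mask = read_mask(sdir / "mask.png")
        cohort.append(SyntheticSubject(cube=cube, mask=mask, subject_id=sid))
    return cohort
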