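"""Ready-made knowledge bases for the bundled phantom applications.

These builders write the human-readable knowledge-base text files for the
two demo applications and are used throughout the test suite:

* ``kidney_kb`` — abdominal CT: threshold-based kidney candidates reviewed
  against anatomical knowledge (soft-tissue intensity range, exclusion of
  dense bone, 50-100 mm lateral offset from the spine, same craniocaudal
  level as the opposite kidney) with morphological post-processing.
* ``ett_kb`` — chest radiograph: trachea and endotracheal tube segmentation,
  two independent carina estimates cross-checked for consistency, a safe
  zone 30-70 mm above the carina, and explained decisions on tube placement.
"""

from __future__ import annotations

from pathlib import Path

from .kb import NODE_LIST_FILENAME, SemanticNetwork, parse_network

__all__ = ["kidney_kb", "kidney_tuning_kb", "ett_kb", "write_kb"]


def write_kb(files: dict[str, str], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    order = list(files)
    (directory / NODE_LIST_FILENAME).write_text(
        "".join(f"{n}\n" for n in order), encoding="utf-8")
    for name, body in files.items():
        (directory / name).write_text(body, encoding="utf-8")
    return directory


_KIDNEY_FILES = {
    "dense_bone": (
        "# dense bone on contrast-enhanced CT\n"
        "IntensityRange 800 2000\n"
    ),
    "spine": (
        "# the spine is the large dense-bone structure\n"
        "IntensityRange 800 2000\n"
    ),
    "kidney_right_init": (
        "# initial right kidney: soft-tissue candidates reviewed by reasoning\n"
        "IntensityRange 300 2000\n"
        "NotPartOf dense_bone\n"
        "RightOf spine 50 100\n"
    ),
    "kidney_left_init": (
        "IntensityRange 300 2000\n"
        "NotPartOf dense_bone\n"
        "LeftOf spine 50 100\n"
        "SameLevelAs kidney_right_init 30\n"
    ),
    "kidney_right": (
        "PartOf kidney_right_init\n"
        "FillHoles\n"
        "MorphClose 3\n"
    ),
    "kidney_left": (
        "PartOf kidney_left_init\n"
        "FillHoles\n"
        "MorphClose 3\n"
    ),
}


def kidney_kb(directory: str | Path, parse: bool = True):
    """Write the kidney knowledge base; returns the parsed network (or the
    directory when ``parse`` is False)."""
    path = write_kb(_KIDNEY_FILES, directory)
    return parse_network(path) if parse else path


def kidney_tuning_kb(directory: str | Path, bits: tuple[int, int] = (0, 2),
                     bounds: tuple[float, float] = (100, 800),
                     parse: bool = True):
    """Kidney knowledge base with the soft-tissue window low bound exposed
    as a tunable parameter (a ``bits``-wide gene between ``bounds``)."""
    files = dict(_KIDNEY_FILES)
    enc = "{%d, %d, %s, %s}" % (bits[0], bits[1], int(bounds[0]), int(bounds[1]))
    files["kidney_left_init"] = files["kidney_left_init"].replace(
        "IntensityRange 300 2000", f"IntensityRange 300 {enc} 2000", 1)
    path = write_kb(files, directory)
    return parse_network(path) if parse else path


_ETT_FILES = {
    "trachea": (
        "# the trachea is the dark air column\n"
        "IntensityRange 0 70\n"
        "MinSize 50\n"
    ),
    "et_tube": (
        "# the endotracheal tube is the bright line\n"
        "IntensityRange 200 255\n"
        "MinSize 10\n"
    ),
    "carina_1": (
        "# carina position predicted by an external model\n"
        "ExternalPredictor\n"
    ),
    "trachea_filled": (
        "# closed trachea column: bridges the gap cut by the bright tube line\n"
        "PartOf trachea\n"
        "MorphClose 2\n"
        "FillHoles\n"
    ),
    "carina_2": (
        "# carina derived from the tracheal bifurcation\n"
        "BifurcationOf trachea_filled\n"
    ),
    "carina_3": (
        "# the two carina estimates must correspond\n"
        "ConsistentWith carina_1 carina_2 10\n"
    ),
    "et_tip": (
        "InferiorTipOf et_tube\n"
    ),
    "et_zone": (
        "# safe zone: 3-7 cm above the carina, within the trachea column\n"
        "BoxAbove carina_3 20 20 30 70\n"
        "PartOf trachea_filled\n"
    ),
    "et_tip_correct": (
        "DecisionInside et_tip et_zone\n"
    ),
    "et_path_correct": (
        "DecisionPathWithin et_tube trachea_filled 0.9\n"
    ),
    "et_tube_correct": (
        "DecisionAnd et_tip_correct et_path_correct\n"
    ),
}


def ett_kb(directory: str | Path, parse: bool = True):
    """Write the endotracheal-tube knowledge base; returns the parsed
    network (or the directory when ``parse`` is False)."""
    path = write_kb(_ETT_FILES, directory)
    return parse_network(path) if parse else path
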