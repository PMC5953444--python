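"""Small JSON/CSV helpers for ellipses, conics and point sets."""

from __future__ import annotations

import json

from .geometry import ConicCoefficients, ParametricEllipse, PointSet


def read_ellipse_json(path) -> ParametricEllipse:
    with open(path) as fh:
        return ParametricEllipse.from_dict(json.load(fh))


def write_ellipse_json(e: ParametricEllipse, path) -> None:
    with open(path, "w") as fh:
        json.dump(e.to_dict(), fh, indent=2)
        fh.write("\n")


def read_conic_json(path) -> ConicCoefficients:
    with open(path) as fh:
        return ConicCoefficients.from_dict(json.load(fh))


def write_conic_json(c: ConicCoefficients, path) -> None:
    with open(path, "w") as fh:
        json.dump(c.to_dict(), fh, indent=2)
        fh.write("\n")


read_points_csv = PointSet.from_csv


def write_points_csv(ps: PointSet, path) -> None:
    ps.to_csv(path)
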