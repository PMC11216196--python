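# annoray

Reproject 2D image annotations onto georeferenced 3D terrain meshes by
per-camera ray casting.

## The problem

Seafloor imagery surveys produce two datasets that do not line up. Biologists
annotate organisms on the raw photographs in web tools such as BIIGLE, and
those annotations are conventionally georeferenced through the vehicle's
hybrid navigation (inertial dead reckoning reset by acoustic USBL fixes) —
accurate to meters at best at depth. Meanwhile, structure-from-motion
photogrammetry builds a 3D terrain mesh from the same photographs whose
*internal* geometry, including the refined ("optical") camera poses, is
consistent to centimeters. Mapping annotations by navigation onto a
centimeter-resolution terrain model therefore smears them by two to three
orders of magnitude more than the model's resolution, duplicates organisms
seen in overlapping images, and breaks any fine-scale spatial analysis.

`annoray` closes the gap: each annotated pixel is turned into a viewing ray
of its photogrammetric camera, the ray is cast against the terrain mesh, and
the **first intersection** is the annotation's 3D position, which is then
georeferenced to WGS84 through a local east-north-up (ENU) frame. Built on
that core are image footprints, duplicate-annotation detection,
disjoint-image selection, reprojection-accuracy statistics, and a synthetic
survey generator that validates the whole pipeline end to end.

## The model

A pinhole camera with Brown radial distortion maps a world point `X` to a
pixel via

```
x_c = R (X − C)                      # world → camera, z_c > 0
(x, y) = (x_c/z_c, y_c/z_c)          # normalized image coordinates
d(r²) = 1 + k₁r² + k₂r⁴ + k₃r⁶       # radial distortion, r² = x² + y²
(u, v) = (c_x + f·x·d, c_y + f·y·d)  # pixels, origin top-left
```

Reprojection is the inverse, without knowing the depth: undistort the pixel
(damped fixed-point inversion of `d`), form the ray
`C + t · Rᵀ(x, y, 1)ᵀ`, and intersect it with the triangle mesh using
Möller–Trumbore under an axis-aligned BVH. Rays hit both triangle sides
(photogrammetric meshes have inconsistent winding); a ray that misses the
mesh — a hole or the model boundary — discards the annotation. Local
coordinates become WGS84 geodetic coordinates through
ENU → ECEF → (lat, lon, h) at a configured anchor.

## Worked example

Generate a synthetic survey (sinusoidal terrain, 3 lawnmower transects,
60 seafloor features annotated in every image that sees them), then
reproject its annotation CSV through its camera file and mesh:

```
$ annoray simulate --out-dir scene --seed 7 --terrain sinusoidal \
      --extent-x 30 --extent-y 8 --n-features 60
scene with 90 cameras, 60 features, 721 annotations written to scene

$ annoray reproject --cameras scene/cameras.json --mesh scene/terrain.ply \
      --annotations scene/annotations.csv --out run \
      --anchor-lat -21.98905 --anchor-lon -176.56844 --anchor-height -1850
reprojected 721, partial 0, discarded 0 of 721 annotations
```

Every annotation ray found the mesh (`discarded` would count rays over
holes), and `run_annotations.geojson` / `run_annotations.csv` now hold one
georeferenced 3D point per annotation; `run_report.json` echoes the counts,
parameters and input digests. Detecting duplicates among the reprojected
points — the same organism annotated on several overlapping images —
with a 5 cm linkage radius:

```
$ annoray duplicates --annotations run_annotations.csv --out dup --radius 0.05
60 duplicate groups; 91.7% of annotations duplicated
```

All 721 sightings collapse onto the 60 planted organisms (one representative
kept per group, so 661 of 721 annotations are duplicates of another image's
annotation — this survey's images overlap heavily). `annoray footprints`
writes each image's ground coverage polygon, `annoray disjoint` greedily
selects images whose footprints overlap below a threshold, and
`annoray evaluate` summarizes reprojection-vs-reference distances by median
and interquartile range.

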