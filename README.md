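# osteorom

Osteological range-of-motion (ROM) mapping for ball-and-socket joints.

Bones alone constrain how a joint can move: a pose of the distal element
is *osteologically viable* if the two bone meshes do not interpenetrate.
Mapping the full set of viable poses — and how it changes with joint
spacing, the bone-only proxy for articular-cartilage thickness — is how
virtual-morphology studies infer the mobility and likely cartilage of
joints whose soft tissue is gone, from fossil hips to disarticulated
museum specimens. `osteorom` is a toolkit for that workflow, aimed at
biomechanists and palaeontologists working with triangle meshes of
skeletal elements.

The pipeline:

1. **Fit** spheres to the socket and head articular surfaces (cylinders
   to shafts), **rearticulate** by superimposing the fitted centres, and
   take the radii difference as the joint spacing.
2. **Rig**: build the joint-centred anatomical coordinate system
   (X abduction/adduction, Y flexion/extension, Z long-axis rotation)
   with the femur toward the ground in the neutral 0°,0°,0° posture.
3. **Sample**: rotate the distal element into every pose of an
   Euler-angle grid (default: FE, LAR −180°..180°, ABAD −90°..90° at 5° —
   197,173 poses, composed as R = R_z(lar)·R_y(fe)·R_x(abad)) and discard
   every pose where the meshes interpenetrate. Three regimes: rotations
   only (3-DOF), plus one static translation (4-DOF, used to sweep joint
   spacing along Y), or plus dynamic translation over the 26 vertices of
   a coarse offset sphere whose radius is the fitted-radii difference
   (6-DOF: a pose is viable if it clears at least one vertex).
4. **Summarize**: map viable poses into the cosine-corrected Euler space
   (abad·cos fe, fe, lar), build a 3-D alpha shape, and report its volume
   in degree³; compare maps, sweep joint spacing to find the mobility
   plateau, and test whether motion-capture joint-angle traces stay
   inside the viable envelope.

Everything is testable offline: `osteorom.synthetic` generates
parametric cup-and-femur joints with known centres, radii and an analytic
clearance-cone angle, plus gait-like angle traces.

## Worked example

```python
import numpy as np
import osteorom as orm

spec = orm.SyntheticJointSpec(mesh_resolution=1000)   # hip-like joint
prox, dist, truth = orm.make_socket_joint(spec)

head = orm.fit_sphere(truth.head_mask.select(dist))
cup = orm.fit_sphere(truth.cup_mask.select(prox))
spacing = orm.joint_spacing_from_radii(cup, head)
print(f"joint spacing: {spacing.value:.3f} mm")

acs = orm.ACS(origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
              y_axis=np.array([0, 1.0, 0]), z_axis=np.array([0, 0, 1.0]))
rig = orm.JointRig(proximal=prox, distal=dist, acs=acs)

line = orm.PoseGrid(fe_range=(0, 0), lar_range=(0, 0),
                    abad_range=(-90, 90), step=5.0)
rom = orm.classify_poses(rig, line, "3dof")
print(f"abduction limit: {rom.viable_poses[:, 0].max():.0f} deg "
      f"(analytic {truth.clearance_cone_half_angle:.2f} deg)")

grid = orm.PoseGrid(step=15.0)
rom3 = orm.classify_poses(rig, grid, "3dof")
vol = orm.alpha_volume(orm.cosine_correct(rom3),
                       orm.default_alpha(grid.step))
print(f"viable poses : {rom3.n_viable} of {grid.size}")
print(f"ROM volume   : {vol.volume:,.0f} deg^3")
```

prints

```
joint spacing: 2.448 mm
abduction limit: 35 deg (analytic 36.42 deg)
viable poses : 525 of 8125
ROM volume   : 1,090,216 deg^3
```

The fitted spheres recover the generator's 20.000 and 17.552 mm radii,
so the spacing is the 2.448 mm ground truth. The collision-based
abduction limit (35°) sits within one 5° grid step of the closed-form
clearance cone (36.42°) at which the femoral neck meets the cup rim. Of
the 8,125 poses of a 15° grid, 525 are viable, and their cosine-corrected
alpha shape enclosed about 1.09 million degree³ of mapped rotations.

The same steps are available from the shell:

```
osteorom synth --out joint/ --resolution 1000
osteorom fit --mesh joint/proximal.ply --mask joint/cup_mask.txt \
             --shape sphere --name acetabulum --out cup.json
osteorom sample --rig rig.yaml --regime 6dof --sphere-radius 2.448 \
                --out rom.csv
osteorom analyze --rig rig.yaml --spacings 0.764,1.183,1.951,2.587 \
                 --step 15 --out analysis/
osteorom compare-trace --trace gait.csv --map rom.csv --out report/
```

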