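# Per-tract tracking parameters for the ten neonatal white-matter tract
# protocols: FA seeding threshold (fa_start), FA propagation threshold
# (fa_stop), turning-angle limit in degrees (max_angle), and the ordered
# ROI plan (op + shape; geometry is drawn per subject by the rater).
tracts:
  CC:
    full_name: corpus callosum
    fa_start: 0.10
    fa_stop: 0.10
    max_angle: 70
    roi_plan:
      - {op: OR, shape: polygon, guidance: tight polygon around the callosal body on the homogeneous mid-sagittal slice}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (transverse pontine fibers, CST, cingulum)}
  CST:
    full_name: corticospinal tract
    fa_start: 0.05
    fa_stop: 0.03
    max_angle: 41
    roi_plan:
      - {op: OR, shape: polygon, guidance: cerebral peduncle at the SCP decussation level (axial)}
      - {op: AND, shape: polygon, guidance: pre-central gyrus fibers on the most cephalad axial slice with the central sulcus}
      - {op: NOT, shape: polygon, guidance: ordered exclusions of non-CST fibers}
  ILF:
    full_name: inferior longitudinal fasciculus
    fa_start: 0.11
    fa_stop: 0.05
    max_angle: 41
    roi_plan:
      - {op: OR, shape: polygon, guidance: whole hemisphere on the coronal slice at the posterior cingulum edge}
      - {op: AND, shape: polygon, guidance: coronal slice in the anterior third of the genu}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (IFO, CST, cingulum)}
  IFO:
    full_name: inferior fronto-occipital fasciculus
    fa_start: 0.11
    fa_stop: 0.05
    max_angle: 41
    roi_plan:
      - {op: OR, shape: polygon, guidance: hemispheric pentagon midway between parieto-occipital sulcus and posterior cingulum edge}
      - {op: AND, shape: polygon, guidance: whole hemisphere on the most anterior coronal slice showing the genu}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (ILF, transverse pontine fibers, CST, cingulum)}
  UNC:
    full_name: uncinate fasciculus
    fa_start: 0.12
    fa_stop: 0.12
    max_angle: 60
    roi_plan:
      - {op: OR, shape: polygon, guidance: entire temporal lobe on the coronal slice in the anterior third of the callosal body}
      - {op: AND, shape: polygon, guidance: inferior frontal lobe on the same coronal slice}
      - {op: NOT, shape: polygon, guidance: ordered exclusions of non-uncinate fibers}
  CG:
    full_name: cingulum (cingulate gyrus part)
    fa_start: 0.05
    fa_stop: 0.05
    max_angle: 70
    roi_plan:
      - {op: OR, shape: polygon, guidance: cone-shaped region from cortical edge to the top of the splenium (coronal)}
      - {op: AND, shape: polygon, guidance: heptagon around the fiber cluster at the middle of the genu (coronal)}
      - {op: NOT, shape: polygon, guidance: ordered exclusions of non-cingulum fibers}
  FX:
    full_name: fornix
    fa_start: 0.12
    fa_stop: 0.12
    max_angle: 60
    roi_plan:
      - {op: OR, shape: polygon, guidance: around the N-shaped bundle on the first axial slice where the fornix arises}
      - {op: AND, shape: polygon, guidance: tight polygon near the hippocampus}
      - {op: AND, shape: oval, width_mm: 6.0, height_mm: 6.0, guidance: oval above the splenium on the homogeneous splenium/genu slice}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (SCP, CC, CST, cingulum)}
  OR:
    full_name: optic radiations
    fa_start: 0.10
    fa_stop: 0.10
    max_angle: 70
    roi_plan:
      - {op: OR, shape: oval, width_mm: 8.0, height_mm: 8.0, guidance: over the lateral geniculate nucleus (coronal)}
      - {op: AND, shape: polygon, guidance: sagittal stratum fibers on the coronal slice at the splenium center}
      - {op: AND, shape: oval, width_mm: 8.0, height_mm: 8.0, guidance: anterior to the coronal marker where voxel clusters join}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (SCP, transverse pontine fibers, CST, cingulum)}
  MCP:
    full_name: middle cerebellar peduncle
    fa_start: 0.13
    fa_stop: 0.05
    max_angle: 41
    roi_plan:
      - {op: OR, shape: oval, width_mm: 4.0, height_mm: 5.0, guidance: left bulge of the MCP bundle (axial)}
      - {op: OR, shape: oval, width_mm: 4.0, height_mm: 5.0, guidance: right bulge, same axial slice}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (SCP, transverse pontine fibers, CST, cingulum)}
  SCP:
    full_name: superior cerebellar peduncle
    fa_start: 0.14
    fa_stop: 0.05
    max_angle: 41
    roi_plan:
      - {op: OR, shape: rectangle, width_mm: 8.0, height_mm: 8.0, guidance: over the decussating SCP on the first axial slice where it appears}
      - {op: NOT, shape: polygon, guidance: ordered exclusions (MCP, transverse pontine fibers, CST, cingulum)}
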