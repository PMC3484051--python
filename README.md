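# airwayct

Non-invasive quantification of **airway remodeling** in small-animal
micro-CT. In allergic-asthma mouse models, structural remodeling of the
bronchi (smooth-muscle enlargement, basement-membrane thickening,
peribronchial fibrosis) adds X-ray attenuation *at the airway wall*,
whereas inflammation raises attenuation diffusely throughout the lung.
`airwayct` measures that difference on respiratory-gated thoracic micro-CT
volumes (typically 46 µm isotropic voxels) and is aimed at preclinical
imaging groups who want a remodeling read-out without histology.

## Method

1. **HU calibration** (optional): a two-point affine map fits in-field air
   and water standards to −1000 and 0 HU; a bone standard, if present, is
   reported as a linearity check.
2. **Bronchial lumen segmentation**: seeded volume growing over the
   bi-threshold band −1024…−900 HU.
3. **Lung segmentation**: seeded volume growing over −900…−100 HU; the
   mean HU over this mask is the *total lung attenuation* (TLA).
4. **Peribronchial shell**: the lumen mask is dilated in 3D by a Euclidean
   radius of 8 voxels; a second lumen-band segmentation inside the dilated
   volume removes all luminal air; a user-supplied mask excludes the
   trachea and mediastinum. The mean HU over the remaining shell is the
   *peribronchial attenuation* (PBA).
5. **Normalization**:

   ```
   normalized PBA = 1 − PBA / TLA
   ```

   Because both attenuations are negative in aerated lung, wall-centred
   attenuation raises normalized PBA, while lung-wide (inflammatory)
   attenuation moves PBA and TLA together and largely cancels. A per-voxel
   variant `y = 1 − x/TLA` produces normalized images.

The package also provides the method-validation statistics (Bland–Altman
bias with ±2 SD limits of agreement, Pearson r, ICC(2,1), Spearman rank
correlation, exact Mann–Whitney–Wilcoxon test) and a synthetic thorax
phantom — a branching airway tree with walls, parenchyma, soft tissue,
calibration cylinders and Gaussian noise — whose ground-truth masks give
oracle values for every pipeline stage.

## Worked example

```python
from airwayct import (PhantomSpec, PipelineConfig, generate_phantom,
                      run_pipeline)

vol, truth = generate_phantom(PhantomSpec())   # 192³, 46 µm, 20 HU noise
cfg = PipelineConfig(lumen_seeds=[truth.lumen_seed.index],
                     lung_seeds=[truth.lung_seed.index],
                     output_dir="out", write_masks=False)
report = run_pipeline(cfg, volume=vol, exclusion=truth.trachea_exclusion_mask)
print(report.summary.as_dict())
```

prints (seed 1):

```
{'tla_hu': -543.5, 'pba_hu': -443.3, 'normalized_pba': 0.1844,
 'lung_voxels': 1682336, 'shell_voxels': 368884}
```

TLA ≈ −543 HU is the mean attenuation of the aerated lung; PBA ≈ −443 HU
is higher (denser) because the shell contains bronchial wall tissue; their
normalized ratio 0.18 is in the range observed for healthy control mice.
The ground truth computed from the phantom's masks gives −543.6 and
−443.3 HU — the pipeline recovers both within a fraction of an HU, and
thickening the walls from 1 to 3 voxels raises normalized PBA
monotonically (0.143 → 0.184 → 0.235) while a lung-wide inflammation halo
leaves it nearly unchanged.

The same pipeline runs from the shell: `airwayct run --config cfg.yaml`,
with subcommands `calibrate`, `segment`, `shell`, `summarize`, `phantom`
and `agreement` for the individual stages.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default phantom from the seed, runs the full pipeline and
both contrast series, compares the recovered attenuations against the
phantom's ground-truth oracle, runs the agreement statistics on simulated
paired measurements, and writes its results JSON to `--out`.
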