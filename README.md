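# vesseltext

Image-text guided retinal vessel segmentation: a dual-branch U-shaped model
combining a CNN branch — with configurable squeeze-and-excitation (SE)
channel attention and pixel-level attention (PLAM) at skip connections —
and a transformer branch whose residual connections carry learnable sigmoid
gates, fused with a caption embedding of each image's text label.

Because the package must run fully offline on one CPU, the neural network is
built on a small numpy reverse-mode autodiff engine that ships inside the
package (`vesseltext.autodiff`), and text embedding defaults to a
deterministic offline stub; a pretrained transformer encoder can be selected
when the `transformers` package is installed.

A procedural generator provides the complete training/evaluation surface:
two synthetic modalities (`cf`: sparse thick radial trunks with a bright
disc blob; `octa`: dense fine mesh with a central avascular zone), binary
masks, and captions built from vessel density / distribution / abnormal-area
descriptors measured on the rendered mask.

## Layout

| module | contents |
|---|---|
| `vesseltext.se_attention` | squeeze / excite / recalibrate, `SEBlock` |
| `vesseltext.plam` | pixel-level attention at skip connections |
| `vesseltext.gated_transformer` | gated residual transformer layers, token-space U branch |
| `vesseltext.text_pipeline` | caption grammar, CSV/XLSX label tables, stub embedder |
| `vesseltext.preprocessing` | grayscale → normalize → CLAHE → gamma chain |
| `vesseltext.metrics` | F1 / Acc / Se / Sp from pixel confusion counts |
| `vesseltext.synthetic_data` | vessel-tree growth, rasterization, dataset writer |
| `vesseltext.model_pipeline` | model assembly, training, evaluation, ablation |
| `vesseltext.autodiff` | numpy autodiff engine (tensors, conv2d, Adam, ...) |

## CLI

```bash
# generate a synthetic OCTA-style dataset (images, masks, labels.csv, manifest)
vesseltext synth --modality octa --size 64 --n-train 40 --n-test 10 --seed 1 --out data/octa

# train (SE after encoder stages, gated transformer branch, stub text encoder)
vesseltext train --data data/octa --se-placement down --epochs 30 --seed 1 --out runs/octa

# evaluate / predict
vesseltext eval --checkpoint runs/octa/checkpoint.npz --data data/octa --out runs/octa/metrics
vesseltext predict --checkpoint runs/octa/checkpoint.npz --data data/octa --out runs/octa/preds

# SE-placement ablation (shared seed and data order across arms)
vesseltext ablate --data data/octa --placements none,down --epochs 5 --seed 1 --out runs/ablation
```

All subcommands accept a `--config` YAML file with `model:` and `train:`
blocks mirroring `ModelConfig` / `TrainConfig`; flags override the file.

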