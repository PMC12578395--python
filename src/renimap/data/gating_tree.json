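{
  "name": "renal-codex-default",
  "description": "Hierarchical marker gating over 26 cardinal markers with 33 leaf cell classes (flow-cytometry-style). Subtree placements that the published supplement alone would pin down are marked in 'placeholders'.",
  "placeholders": [
    "NK cell branch position (CD56 tested before CD16 in the CD14- arm)",
    "other leukocyte catch-all under CD11c-",
    "structural marker order below Claudin1"
  ],
  "root": {
    "marker": "CD45",
    "positive": {
      "marker": "CD3",
      "positive": {
        "marker": "TCRgd",
        "positive": {"class": "gd T cell"},
        "negative": {
          "marker": "CD4",
          "positive": {
            "marker": "FOXP3",
            "positive": {"class": "CD4 Treg"},
            "negative": {"class": "CD4 T cell"}
          },
          "negative": {
            "marker": "CD8",
            "positive": {
              "marker": "FOXP3",
              "positive": {"class": "CD8 Treg"},
              "negative": {"class": "CD8 T cell"}
            },
            "negative": {"class": "DN T cell"}
          }
        }
      },
      "negative": {
        "marker": "CD20",
        "positive": {"class": "B cell"},
        "negative": {
          "marker": "CD138",
          "positive": {
            "marker": "CD38",
            "positive": {"class": "plasmablast"},
            "negative": {"class": "plasma cell"}
          },
          "negative": {
            "marker": "CD14",
            "positive": {
              "marker": "CD16",
              "positive": {
                "marker": "HLAII",
                "positive": {"class": "HLAII+ inflammatory monocyte"},
                "negative": {"class": "HLAII- inflammatory monocyte"}
              },
              "negative": {
                "marker": "CD163",
                "positive": {
                  "marker": "MerTK",
                  "positive": {"class": "CD14+CD163+MerTK+ macrophage"},
                  "negative": {"class": "CD14+CD163+ macrophage"}
                },
                "negative": {
                  "marker": "MerTK",
                  "positive": {"class": "CD14+MerTK+ macrophage"},
                  "negative": {"class": "CD14+ macrophage"}
                }
              }
            },
            "negative": {
              "marker": "CD56",
              "positive": {"class": "NK cell"},
              "negative": {
                "marker": "CD16",
                "positive": {"class": "CD16+ macrophage"},
                "negative": {
                  "marker": "BDCA2",
                  "positive": {"class": "plasmacytoid DC"},
                  "negative": {
                    "marker": "BDCA1",
                    "positive": {"class": "conventional DC"},
                    "negative": {
                      "marker": "CD11c",
                      "positive": {"class": "monocyte-derived macrophage"},
                      "negative": {"class": "other leukocyte"}
                    }
                  }
                }
              }
            }
          }
        }
      }
    },
    "negative": {
      "marker": "CD14",
      "positive": {
        "marker": "CD163",
        "positive": {
          "marker": "MerTK",
          "positive": {"class": "CD45- CD163+MerTK+ macrophage"},
          "negative": {"class": "CD45- CD163+ macrophage"}
        },
        "negative": {
          "marker": "MerTK",
          "positive": {"class": "CD45- MerTK+ macrophage"},
          "negative": {"class": "CD45- CD14+ macrophage"}
        }
      },
      "negative": {
        "marker": "CD10",
        "positive": {"class": "proximal tubule"},
        "negative": {
          "marker": "MUC1",
          "positive": {"class": "distal tubule"},
          "negative": {
            "marker": "Claudin1",
            "positive": {"class": "Claudin1+ tubule epithelium"},
            "negative": {
              "marker": "CD31",
              "positive": {"class": "endothelium"},
              "negative": {
                "marker": "Synaptopodin",
                "positive": {"class": "podocyte"},
                "negative": {
                  "marker": "SMA",
                  "positive": {"class": "smooth muscle"},
                  "negative": {
                    "marker": "Cytokeratin",
                    "positive": {"class": "epithelium other"},
                    "negative": {
                      "marker": "CD90",
                      "positive": {"class": "fibroblast"},
                      "negative": {"class": null}
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
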