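# Per-year decision thresholds for the two-stage canopy classifier.
#
# Stage I (vegetation delineation): a pixel is non-vegetation iff
#   NDWI > ndwi_min  AND  NDVI < ndvi_max        (strict inequalities)
# Stage II (tree / grassland separation) within vegetation:
#   Node 1: non-vegetation iff brightness > brightness_nonveg_min
#           OR the pixel was non-vegetation after Stage I
#   Node 2: tree iff brightness < brightness_tree_max
#           OR texture > texture_tree_min
#   remaining pixels: grassland
#
# Brightness is in DN^2 units (sum of squared 8-bit band values); texture is
# co-occurrence contrast over a 3x3 window at 32 gray levels. Values are
# calibrated per acquisition year because sensors, solar geometry and
# phenology differ between surveys; edit by hand to refine.
years:
  "2013":
    pixel_size_m: 1.0
    ndwi_min: 0.0
    ndvi_max: -0.05
    brightness_nonveg_min: 150000
    brightness_tree_max: 50000
    texture_tree_min: 50
    sieve_min_area_m2: 9.0
  "2015":
    pixel_size_m: 1.0
    ndwi_min: -0.05
    ndvi_max: 0.05
    brightness_nonveg_min: 150000
    brightness_tree_max: 70000
    texture_tree_min: 50
    sieve_min_area_m2: 9.0
  "2017":
    pixel_size_m: 1.0
    ndwi_min: -0.1
    ndvi_max: 0.15
    brightness_nonveg_min: 120000
    brightness_tree_max: 80000
    texture_tree_min: 50
    sieve_min_area_m2: 9.0
  "2019":
    pixel_size_m: 0.6
    ndwi_min: -0.05
    ndvi_max: 0.05
    brightness_nonveg_min: 100000
    brightness_tree_max: 55000
    texture_tree_min: 50
    sieve_min_area_m2: 3.24
  "2021":
    pixel_size_m: 0.6
    ndwi_min: 0.0
    ndvi_max: 0.0
    brightness_nonveg_min: 120000
    brightness_tree_max: 70000
    texture_tree_min: 50
    sieve_min_area_m2: 3.24
defaults:
  connectivity: 8
  texture_window: 3
  texture_statistic: contrast
  texture_levels: 32
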