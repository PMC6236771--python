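import numpy as np
import pytest

from lucad.imaging import CTSlice


def make_ct(pixels, spacing=1.0, slice_id="test"):
    """CTSlice from a raw array, clipped into [0, 1]."""
    return CTSlice(np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0),
                   pixel_spacing_mm=spacing, slice_id=slice_id)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def disk_image(shape=(64, 64), center=(32, 32), radius=10,
               fg=0.9, bg=0.1, noise=0.0, seed=0):
    """Bright disk on a dark background, optionally with Gaussian noise."""
    img = np.full(shape, bg)
    truth = disk_mask(shape, center, radius)
    img[truth] = fg
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return np.clip(img, 0, 1), truth


def write_synthetic_dicom(path, pixel_array, spacing=None, slope=None, intercept=None):
    """Write a minimal single-frame grayscale DICOM for round-trip tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    arr = np.asarray(pixel_array, dtype=np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    if spacing is not None:
        ds.PixelSpacing = [spacing, spacing]
    if slope is not None:
        ds.RescaleSlope = slope
    if intercept is not None:
        ds.RescaleIntercept = intercept
    ds.save_as(str(path), enforce_file_format=True)
    return path


@pytest.fixture(scope="session")
def phantom_slice():
    """One deterministic phantom slice with two nodules and full truth."""
    from lucad.phantom import PhantomSpec, make_slice

    spec = PhantomSpec(image_size=256, size_range_mm=(6.0, 18.0))
    return make_slice(spec, seed=7, nodules=[(14.0, "malign"), (9.0, "benign")])
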