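registry,keyword,value,designator,meaning
SCT,Tumor,108369006,SCT,Tumor
SCT,Nodule,27925004,SCT,Nodule
SCT,Lung,39607008,SCT,Lung
SCT,Liver,10200004,SCT,Liver
SCT,ThoracicStructure,51185008,SCT,Thoracic structure
SCT,Tissue,85756007,SCT,Tissue
SCT,Normal,17621005,SCT,Normal
SCT,MorphologicallyAbnormalStructure,49755003,SCT,Morphologically Abnormal Structure
SCT,AnatomicalStructure,123037004,SCT,Anatomical Structure
SCT,FindingSite,363698007,SCT,Finding site
SCT,AssociatedMorphology,116676008,SCT,Associated morphology
SCT,Present,52101004,SCT,Present
SCT,Absent,2667000,SCT,Absent
SCT,Imaging,363679005,SCT,Imaging
SCT,Area,42798000,SCT,Area
SCT,Diameter,81827009,SCT,Diameter
SCT,Volume,118565006,SCT,Volume
DCM,ImagingMeasurementReport,126000,DCM,Imaging Measurement Report
DCM,ImagingMeasurements,126010,DCM,Imaging Measurements
DCM,MeasurementGroup,125007,DCM,Measurement Group
DCM,TrackingIdentifier,112039,DCM,Tracking Identifier
DCM,TrackingUniqueIdentifier,112040,DCM,Tracking Unique Identifier
DCM,Finding,121071,DCM,Finding
DCM,ImageRegion,111030,DCM,Image Region
DCM,ReferencedSegment,121191,DCM,Referenced Segment
DCM,LanguageOfContentItemAndDescendants,121049,DCM,Language of Content Item and Descendants
DCM,ObserverType,121005,DCM,Observer Type
DCM,Person,121006,DCM,Person
DCM,Device,121007,DCM,Device
DCM,PersonObserverName,121008,DCM,Person Observer Name
DCM,DeviceObserverUID,121012,DCM,Device Observer UID
DCM,ProcedureReported,121058,DCM,Procedure reported
DCM,SourceImageForImageProcessingOperation,121322,DCM,Source image for image processing operation
DCM,SourceImage,121324,DCM,Source Image
DCM,ProbabilityOfCancer,111047,DCM,Probability of cancer
UCUM,Millimeter,mm,UCUM,mm
UCUM,SquareMillimeter,mm2,UCUM,square millimeter
UCUM,CubicMillimeter,mm3,UCUM,cubic millimeter
UCUM,Micrometer,um,UCUM,micrometer
UCUM,NoUnits,1,UCUM,no units
UCUM,Percent,%,UCUM,percent
RFC5646,English,en,RFC5646,English
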