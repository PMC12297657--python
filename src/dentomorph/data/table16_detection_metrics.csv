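model,metric,before,after
YOLOv8,mAP,0.783,0.845
YOLOv8,Precision,0.812,0.867
YOLOv8,Recall,0.773,0.838
YOLOv8,F1-Score,0.792,0.852
Faster R-CNN,mAP,0.745,0.821
Faster R-CNN,Precision,0.781,0.842
Faster R-CNN,Recall,0.729,0.812
Faster R-CNN,F1-Score,0.754,0.827
RetinaNet,mAP,0.738,0.804
RetinaNet,Precision,0.771,0.831
RetinaNet,Recall,0.723,0.795
RetinaNet,F1-Score,0.746,0.813
DETR,mAP,0.721,0.792
DETR,Precision,0.758,0.817
DETR,Recall,0.712,0.785
DETR,F1-Score,0.734,0.801
EfficientDet,mAP,0.752,0.824
EfficientDet,Precision,0.775,0.843
EfficientDet,Recall,0.738,0.813
EfficientDet,F1-Score,0.756,0.828
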